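"""Synthetic orthogroup evolution with ground truth.

Families are evolved on a pure-birth (Yule) ultrametric tree from an
ancestral protein containing planted coiled-coil segments.  The model:

* **Substitutions** — per branch and site, Poisson with mean
  ``branch_length x region multiplier x site rate``; site rates are drawn
  once per site from a gamma distribution with shape ``gamma_shape`` and
  mean 1 (rates-across-sites).  Replacement residues are uniform over the
  19 alternatives — the Poisson model the divergence estimator assumes —
  except inside planted segments, where with probability
  ``heptad_preservation_prob`` the new residue is redrawn from the heptad
  class of its register position (hydrophobic at a/d, charged/polar at
  e/g), emulating selection that preserves coiled-coil character without
  preserving sequence.
* **Indels** — a Poisson event process per branch with separate rates
  inside and outside the planted segments and geometric lengths;
  deletions never straddle a segment boundary (configurable), emulating
  selection against coil disruption.

Every indel is threaded through a master column system, so the generator
emits the *true* alignment alongside tip sequences, a per-branch event
log (replaying the log from the ancestor reproduces every tip exactly),
per-tip planted segment coordinates, and oracle score profiles (score
``1 - eps`` inside planted segments, ``eps`` outside).  Oracle profiles
make metric correctness testable independently of any predictor; the
heptad scorer can be run on the same sequences to test the predictor
itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .coilscore import HYDROPHOBIC, POLAR_CHARGED, heptad_cc_score
from .io import AMINO_ACIDS, OrthogroupAlignment, Phylogeny, ProteinRecord, ScoreProfile

_AA = np.array(list(AMINO_ACIDS))
_HYDRO = sorted(HYDROPHOBIC)
_POLAR = sorted(POLAR_CHARGED)
_AD_REGISTERS = (0, 3)
_EG_REGISTERS = (4, 6)


class _RetrySimulation(Exception):
    """Internal: the indel process degenerated; resample the family."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated family.

    Defaults describe a synaptonemal-complex-like family: a 500-residue
    ancestor on a 12-taxon tree, two coiled-coil segments covering half
    the protein, and a five-fold indel-rate suppression inside them.
    """

    seed: int = 0
    n_tips: int = 12
    tree_height: float = 0.8
    #: rescale branch lengths so the mean pairwise tip distance equals this
    target_mean_pairwise: float | None = None
    newick: str | None = None  # explicit tree; overrides n_tips/height
    ancestral_length: int = 500
    cc_segments: tuple[tuple[int, int], ...] = ((50, 175), (200, 325))
    subs_rate_in: float = 1.0
    subs_rate_out: float = 1.0
    gamma_shape: float = 2.0
    #: expected indel events per site per unit branch length
    indel_rate_in: float = 0.008
    indel_rate_out: float = 0.04
    #: geometric length parameter (mean length = 1/p)
    indel_length_p: float = 1 / 3
    heptad_preservation_prob: float = 0.9
    #: SD of the truncated-Gaussian noise on oracle profiles
    profile_noise_sd: float = 0.05
    allow_boundary_split: bool = False
    paralog_species: str | None = None
    orthogroup_id: str = "sim"

    def validate(self) -> None:
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.ancestral_length < 1:
            raise ValueError("ancestral_length must be >= 1")
        for rate in (self.indel_rate_in, self.indel_rate_out,
                     self.subs_rate_in, self.subs_rate_out):
            if rate < 0:
                raise ValueError("rates must be >= 0")
        last = 0
        for s, e in self.cc_segments:
            if not (last <= s < e <= self.ancestral_length):
                raise ValueError(
                    "cc_segments must be disjoint, ordered and within "
                    f"[0, {self.ancestral_length})"
                )
            last = e


@dataclass
class SimulatedFamily:
    """Ground-truth output of :func:`simulate_family`."""

    config: SimConfig
    alignment: OrthogroupAlignment
    tree: Phylogeny
    #: per-branch events in application (preorder) order; tuples are
    #: ("sub", branch, col, residue), ("del", branch, (cols...)) or
    #: ("ins", branch, anchor_col, ((col, residue)...))
    events: list[tuple]
    tip_segments: dict[str, list[tuple[int, int]]]
    profiles: dict[str, ScoreProfile]
    ancestral: tuple[tuple[int, str], ...]
    master_order: tuple[int, ...]
    visible_columns: tuple[int, ...]
    segment_column: np.ndarray  # bool per master column id

    @property
    def n_indel_events(self) -> int:
        return sum(1 for ev in self.events if ev[0] in ("del", "ins"))

    @property
    def n_substitution_events(self) -> int:
        """Columns changed per branch (multiple hits collapse to one log
        entry; see ``n_substitution_draws`` for the raw Poisson count)."""
        return sum(1 for ev in self.events if ev[0] == "sub")

    n_substitution_draws: int = 0

    def members(self) -> list[ProteinRecord]:
        """Unaligned tip proteins (plus injected paralog copies, if any)."""
        out = [
            ProteinRecord(f"{sp}|{self.alignment.orthogroup_id}", sp, seq)
            for sp, seq in (
                (sp, self.alignment.ungapped(sp)) for sp in self.alignment.rows
            )
        ]
        if self.config.paralog_species in self.alignment.rows:
            sp = self.config.paralog_species
            out.append(
                ProteinRecord(
                    f"{sp}|{self.alignment.orthogroup_id}_p2",
                    sp,
                    self.alignment.ungapped(sp),
                )
            )
        return out

    def heptad_profiles(self, window: int = 28) -> dict[str, ScoreProfile]:
        return {
            sp: heptad_cc_score(self.alignment.ungapped(sp), window=window,
                                protein_id=f"{sp}|{self.alignment.orthogroup_id}",
                                species=sp)
            for sp in self.alignment.rows
        }

    def replay(self) -> bool:
        """Re-apply the event log from the ancestral sequence and check
        that every tip sequence and gap pattern is reproduced exactly."""
        events_by_branch: dict[str, list[tuple]] = {}
        for ev in self.events:
            events_by_branch.setdefault(ev[1], []).append(ev)

        order = {c: i for i, c in enumerate(self.master_order)}
        visible = set(self.visible_columns)
        root_state = dict(self.ancestral)

        def apply_branch(state: dict[int, str], branch: str) -> dict[int, str]:
            state = dict(state)
            for ev in events_by_branch.get(branch, ()):
                kind = ev[0]
                if kind == "sub":
                    _, _, col, res = ev
                    assert col in state
                    state[col] = res
                elif kind == "del":
                    for col in ev[2]:
                        del state[col]
                else:
                    for col, res in ev[3]:
                        state[col] = res
            return state

        states = {self.tree.tree.seed_node: root_state}
        ok = True
        for node in self.tree.tree.preorder_node_iter():
            if node is self.tree.tree.seed_node:
                continue
            label = _sim_label(node)
            states[node] = apply_branch(states[node.parent_node], label)
            if node.is_leaf():
                sp = node.taxon.label
                cols = sorted(states[node], key=order.__getitem__)
                seq = "".join(states[node][c] for c in cols)
                ok &= seq == self.alignment.ungapped(sp)
                row_cols = {c for c in cols if c in visible}
                aligned_cols = {
                    self.visible_columns[i]
                    for i, ch in enumerate(self.alignment.rows[sp])
                    if ch != "-"
                }
                ok &= row_cols == aligned_cols
        return ok

    def true_indel_events(self) -> list[tuple[str, str, int, int]]:
        """Logged indel events mapped to alignment coordinates:
        (branch, kind, start, end) over visible columns; events whose
        columns were later deleted everywhere are dropped."""
        pos = {c: i for i, c in enumerate(self.visible_columns)}
        out = []
        for ev in self.events:
            if ev[0] == "del":
                cols = [pos[c] for c in ev[2] if c in pos]
            elif ev[0] == "ins":
                cols = [pos[c] for c, _ in ev[3] if c in pos]
            else:
                continue
            if cols:
                out.append((ev[1], ev[0], min(cols), max(cols) + 1))
        return out


def _sim_label(node) -> str:
    """Stable branch label: the sorted tip set below the node (matches the
    labelling used by indel inference)."""
    if node.is_leaf():
        return node.taxon.label
    return ",".join(sorted(lf.taxon.label for lf in node.leaf_iter()))


# ---------------------------------------------------------------------------
# Trees


def simulate_tree(n_tips: int, height: float, seed: int = 0) -> Phylogeny:
    """Pure-birth (Yule) topology with branch lengths scaled so every
    root-to-tip path equals ``height``.  Deterministic given ``seed``."""
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if height <= 0:
        raise ValueError("height must be > 0")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    depth = {tree.seed_node: 0.0}
    active = [tree.seed_node.new_child(), tree.seed_node.new_child()]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        depth[node] = t
        active.extend([node.new_child(), node.new_child()])
    total = t + rng.exponential(1.0 / n_tips)
    width = len(str(n_tips))
    for j, node in enumerate(active):
        depth[node] = total
        node.taxon = tns.new_taxon(label=f"t{j + 1:0{width}d}")
    scale = height / total
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            node.edge.length = None
        else:
            node.edge.length = (depth[node] - depth[node.parent_node]) * scale
    return Phylogeny(tree)


def mean_pairwise_path(phylogeny: Phylogeny) -> float:
    """Mean patristic distance over all unordered tip pairs."""
    pdm = phylogeny.tree.phylogenetic_distance_matrix()
    taxa = list(phylogeny.tree.taxon_namespace)
    dists = [
        pdm.patristic_distance(taxa[i], taxa[j])
        for i in range(len(taxa))
        for j in range(i + 1, len(taxa))
    ]
    return float(np.mean(dists))


def _scale_branches(phylogeny: Phylogeny, factor: float) -> None:
    for node in phylogeny.tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length *= factor


# ---------------------------------------------------------------------------
# Family simulation


class _Columns:
    """Master column registry: region flag, heptad register and site rate
    per column id."""

    def __init__(self, rng, config: SimConfig):
        L = config.ancestral_length
        self.in_segment = np.zeros(L, dtype=bool)
        self.register = np.full(L, -1, dtype=int)
        for s, e in config.cc_segments:
            self.in_segment[s:e] = True
            self.register[s:e] = (np.arange(e - s)) % 7
        shape = config.gamma_shape
        self.rate = rng.gamma(shape, 1.0 / shape, size=L)
        self._rng = rng
        self._shape = shape

    def new_columns(self, n: int, in_segment: bool, start_register: int) -> np.ndarray:
        ids = np.arange(len(self.rate), len(self.rate) + n)
        self.in_segment = np.concatenate(
            [self.in_segment, np.full(n, in_segment)]
        )
        regs = (
            (start_register + 1 + np.arange(n)) % 7 if in_segment else np.full(n, -1)
        )
        self.register = np.concatenate([self.register, regs])
        self.rate = np.concatenate(
            [self.rate, self._rng.gamma(self._shape, 1.0 / self._shape, size=n)]
        )
        return ids


def _draw_residue(rng, in_segment: bool, register: int) -> str:
    if in_segment and register in _AD_REGISTERS:
        return _HYDRO[int(rng.integers(len(_HYDRO)))]
    if in_segment and register in _EG_REGISTERS:
        return _POLAR[int(rng.integers(len(_POLAR)))]
    return str(_AA[int(rng.integers(20))])


def _substitute(rng, residue: str, in_segment: bool, register: int,
                preserve_prob: float) -> str:
    if (
        in_segment
        and register in _AD_REGISTERS + _EG_REGISTERS
        and rng.random() < preserve_prob
    ):
        pool = _HYDRO if register in _AD_REGISTERS else _POLAR
        choices = [c for c in pool if c != residue]
        if choices:
            return choices[int(rng.integers(len(choices)))]
    choices = [c for c in AMINO_ACIDS if c != residue]
    return choices[int(rng.integers(19))]


def simulate_family(config: SimConfig) -> SimulatedFamily:
    """Evolve one family under ``config``.

    If the indel process deletes a lineage's entire sequence the family
    is resampled with a warning-free derived seed, up to 10 times.
    """
    config.validate()
    master_rng = np.random.default_rng(config.seed)
    for _attempt in range(10):
        attempt_seed = int(master_rng.integers(2**31 - 1))
        try:
            return _simulate_once(config, attempt_seed)
        except _RetrySimulation:
            continue
    raise RuntimeError(
        "indel process repeatedly deleted an entire sequence; lower the "
        "indel rates or lengthen the ancestor"
    )


def _simulate_once(config: SimConfig, seed: int) -> SimulatedFamily:
    rng = np.random.default_rng(seed)

    if config.newick is not None:
        phylogeny = Phylogeny.from_newick(config.newick)
    else:
        phylogeny = simulate_tree(
            config.n_tips, config.tree_height, int(rng.integers(2**31 - 1))
        )
    if config.target_mean_pairwise is not None:
        current = mean_pairwise_path(phylogeny)
        _scale_branches(phylogeny, config.target_mean_pairwise / current)
    tree = phylogeny.tree

    columns = _Columns(rng, config)
    master_order: list[int] = list(range(config.ancestral_length))
    ancestral = {
        c: _draw_residue(rng, bool(columns.in_segment[c]), int(columns.register[c]))
        for c in master_order
    }

    events: list[tuple] = []
    n_draws = 0
    # per-node state: (ordered column id list, col -> residue)
    states: dict = {tree.seed_node: (list(master_order), dict(ancestral))}

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        branch = _sim_label(node)
        bl = node.edge.length or 0.0
        cols, residues = states[node.parent_node]
        cols = list(cols)
        residues = dict(residues)

        # substitutions
        if bl > 0:
            col_arr = np.asarray(cols)
            in_seg = columns.in_segment[col_arr]
            mult = np.where(in_seg, config.subs_rate_in, config.subs_rate_out)
            lam = bl * mult * columns.rate[col_arr]
            n_subs = rng.poisson(lam)
            n_draws += int(n_subs.sum())
            for idx in np.flatnonzero(n_subs):
                c = cols[idx]
                res = residues[c]
                for _ in range(int(n_subs[idx])):
                    res = _substitute(
                        rng, res, bool(columns.in_segment[c]),
                        int(columns.register[c]),
                        config.heptad_preservation_prob,
                    )
                residues[c] = res
                events.append(("sub", branch, c, res))

        # indels
        if bl > 0:
            n_in = int(np.sum(columns.in_segment[np.asarray(cols)]))
            n_out = len(cols) - n_in
            plan = ["in"] * int(rng.poisson(config.indel_rate_in * n_in * bl))
            plan += ["out"] * int(rng.poisson(config.indel_rate_out * n_out * bl))
            rng.shuffle(plan)
            for region in plan:
                want = region == "in"
                candidates = [
                    i for i, c in enumerate(cols) if columns.in_segment[c] == want
                ]
                if not candidates:
                    continue
                pos = candidates[int(rng.integers(len(candidates)))]
                length = int(rng.geometric(config.indel_length_p))
                if rng.random() < 0.5:  # deletion
                    run_end = pos
                    while (
                        run_end < len(cols)
                        and run_end - pos < length
                        and (
                            config.allow_boundary_split
                            or columns.in_segment[cols[run_end]] == want
                        )
                    ):
                        run_end += 1
                    doomed = cols[pos:run_end]
                    if not doomed:
                        continue
                    if len(doomed) >= len(cols):
                        raise _RetrySimulation
                    del cols[pos:run_end]
                    for c in doomed:
                        del residues[c]
                    events.append(("del", branch, tuple(doomed)))
                else:  # insertion after the chosen residue
                    anchor = cols[pos]
                    new_ids = columns.new_columns(
                        length, want, int(columns.register[anchor])
                    )
                    payload = []
                    for c in new_ids:
                        res = _draw_residue(
                            rng, want, int(columns.register[c])
                        )
                        residues[int(c)] = res
                        payload.append((int(c), res))
                    cols[pos + 1 : pos + 1] = [int(c) for c in new_ids]
                    mpos = master_order.index(anchor)
                    master_order[mpos + 1 : mpos + 1] = [int(c) for c in new_ids]
                    events.append(("ins", branch, anchor, tuple(payload)))

        if node.is_leaf() and not cols:
            raise _RetrySimulation
        states[node] = (cols, residues)

    # assemble the true alignment over columns surviving in >= 1 tip
    tips = [nd for nd in tree.leaf_node_iter()]
    tip_cols = {nd.taxon.label: states[nd] for nd in tips}
    present: set[int] = set()
    for colset, _ in tip_cols.values():
        present.update(colset)
    visible = [c for c in master_order if c in present]
    vis_index = {c: i for i, c in enumerate(visible)}

    rows: dict[str, str] = {}
    ids: dict[str, str] = {}
    tip_segments: dict[str, list[tuple[int, int]]] = {}
    profiles: dict[str, ScoreProfile] = {}
    for nd in tips:
        sp = nd.taxon.label
        colset, residues = tip_cols[sp]
        ordered = sorted(colset, key=vis_index.__getitem__)
        row = ["-"] * len(visible)
        for c in ordered:
            row[vis_index[c]] = residues[c]
        rows[sp] = "".join(row)
        ids[sp] = f"{sp}|{config.orthogroup_id}"
        seg_mask = columns.in_segment[np.asarray(ordered)]
        tip_segments[sp] = _mask_to_intervals(seg_mask)
        eps = np.abs(rng.normal(0.0, config.profile_noise_sd, size=len(ordered)))
        scores = np.where(seg_mask, 1.0 - eps, eps)
        np.clip(scores, 0.0, 1.0, out=scores)
        profiles[sp] = ScoreProfile(
            ids[sp], sp, "".join(residues[c] for c in ordered), scores, "coiled_coil"
        )

    alignment = OrthogroupAlignment(config.orthogroup_id, rows, ids)
    return SimulatedFamily(
        config=config,
        alignment=alignment,
        tree=phylogeny,
        events=events,
        tip_segments=tip_segments,
        profiles=profiles,
        ancestral=tuple(sorted(ancestral.items())),
        master_order=tuple(master_order),
        visible_columns=tuple(visible),
        segment_column=columns.in_segment,
        n_substitution_draws=n_draws,
    )


def _mask_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j < n and mask[j]:
            j += 1
        out.append((i, j))
        i = j
    return out


# ---------------------------------------------------------------------------
# Proteome-scale presets


def sc_like_config(seed: int, orthogroup_id: str = "sc_like", n_tips: int = 12,
                   length: int = 450) -> SimConfig:
    """A family with the synaptonemal-complex signature: mean pairwise
    divergence ~1.5 substitutions/site, two conserved coiled-coil
    segments covering ~2/3 of the protein, and indels suppressed
    five-fold inside them."""
    frac = length / 450
    segments = tuple(
        (round(s * frac), round(e * frac)) for s, e in ((60, 200), (230, 400))
    )
    return SimConfig(
        seed=seed,
        n_tips=n_tips,
        target_mean_pairwise=1.5,
        ancestral_length=length,
        cc_segments=segments,
        indel_rate_in=0.004,
        indel_rate_out=0.02,
        heptad_preservation_prob=0.9,
        orthogroup_id=orthogroup_id,
    )


def background_config(seed: int, rng: np.random.Generator,
                      orthogroup_id: str = "bg", n_tips: int = 12) -> SimConfig:
    """A typical proteome family: modest divergence (mean pairwise drawn
    from U(0.15, 0.7) substitutions/site), indels unsuppressed and an
    order of magnitude more frequent than in SC-like families, and at
    most a short, weakly preserved coiled-coil segment (30% of
    families)."""
    length = int(rng.integers(200, 601))
    segments: tuple[tuple[int, int], ...] = ()
    if rng.random() < 0.3:
        seg_len = int(rng.integers(40, 91))
        start = int(rng.integers(0, max(1, length - seg_len)))
        segments = ((start, start + seg_len),)
    indel_rate = float(rng.uniform(0.08, 0.2))
    return SimConfig(
        seed=seed,
        n_tips=n_tips,
        target_mean_pairwise=float(rng.uniform(0.15, 0.7)),
        ancestral_length=length,
        cc_segments=segments,
        indel_rate_in=indel_rate,
        indel_rate_out=indel_rate,
        indel_length_p=0.1,
        allow_boundary_split=True,
        heptad_preservation_prob=0.5,
        orthogroup_id=orthogroup_id,
    )


def simulate_proteome(
    n_background: int,
    n_planted: int,
    seed: int = 0,
    n_tips: int = 12,
) -> tuple[list[SimulatedFamily], pd.DataFrame]:
    """Simulate a screening test bed: ``n_planted`` SC-like families
    hidden among ``n_background`` ordinary ones.

    Returns the families plus a truth table labelling each orthogroup.
    Deterministic given ``seed``.
    """
    if n_background < 0 or n_planted < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    families = []
    records = []
    for i in range(n_planted):
        cfg = sc_like_config(
            int(rng.integers(2**31 - 1)), f"OG_planted_{i:03d}", n_tips=n_tips
        )
        families.append(simulate_family(cfg))
        records.append({"orthogroup_id": cfg.orthogroup_id, "planted": True})
    for i in range(n_background):
        cfg = background_config(
            int(rng.integers(2**31 - 1)), rng, f"OG_bg_{i:04d}", n_tips=n_tips
        )
        families.append(simulate_family(cfg))
        records.append({"orthogroup_id": cfg.orthogroup_id, "planted": False})
    return families, pd.DataFrame.from_records(records)
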