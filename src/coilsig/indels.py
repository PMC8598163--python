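"""Phylogeny-aware indel census and depletion testing.

The manual procedure this automates: scan an orthogroup alignment for
gap blocks, count indel events along the phylogeny, classify every
alignment position as indel-containing or indel-lacking and as inside or
outside the reference species' coiled-coil, and test for depletion of
indels inside coiled-coils with a two-sided Fisher exact test on the
resulting 2x2 table.

Event inference treats the gap presence/absence pattern of each maximal
column interval with a constant pattern ("region block") as a binary
character and reconstructs the minimum number of state changes with
Fitch parsimony.  Events are unpolarised (insertion vs. deletion is not
called): polarisation would require an outgroup assumption, and the
depletion test only needs positions with indels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coilscore import CoilDomain
from .errors import ConsistencyError
from .io import GAP, OrthogroupAlignment, Phylogeny

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GapBlock:
    """A maximal run of gap characters in one species' aligned row."""

    species: str
    start: int
    end: int


@dataclass(frozen=True)
class IndelEvent:
    """One inferred indel event: a column interval and the tree branch
    (identified by the label of the child node) on which the gap state
    changes.  ``gap_gained`` records the direction of the state change on
    that branch (used for merging), not insertion/deletion polarity.
    """

    start: int
    end: int
    branch: str
    gap_gained: bool

    def covers(self, column: int) -> bool:
        return self.start <= column < self.end


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Alignment positions with indels / total, inside vs outside the
    coiled-coil."""

    indel_in: int
    total_in: int
    indel_out: int
    total_out: int

    def __post_init__(self) -> None:
        cells = (self.indel_in, self.total_in, self.indel_out, self.total_out)
        if any(c < 0 for c in cells):
            raise ValueError("negative cell count")
        if self.indel_in > self.total_in or self.indel_out > self.total_out:
            raise ValueError("indel count exceeds total positions")

    def __add__(self, other: "ContingencyTable2x2") -> "ContingencyTable2x2":
        return ContingencyTable2x2(
            self.indel_in + other.indel_in,
            self.total_in + other.total_in,
            self.indel_out + other.indel_out,
            self.total_out + other.total_out,
        )


@dataclass
class ColumnLabels:
    """Per-column classification for the columns entering the census."""

    columns: np.ndarray
    indel_containing: np.ndarray
    inside_cc: np.ndarray


def find_gap_blocks(msa: OrthogroupAlignment) -> list[GapBlock]:
    """All maximal per-species gap runs, in (species, start) order."""
    blocks = []
    for sp, row in msa.rows.items():
        i = 0
        n = len(row)
        while i < n:
            if row[i] != GAP:
                i += 1
                continue
            j = i
            while j < n and row[j] == GAP:
                j += 1
            blocks.append(GapBlock(sp, i, j))
            i = j
    return blocks


def all_gap_columns(msa: OrthogroupAlignment) -> np.ndarray:
    """Columns gapped in every species (excluded from downstream counts)."""
    rows = list(msa.rows.values())
    return np.array(
        [c for c in range(msa.n_columns) if all(r[c] == GAP for r in rows)],
        dtype=int,
    )


# ---------------------------------------------------------------------------
# Fitch parsimony


def _node_label(node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return ",".join(sorted(lf.taxon.label for lf in node.leaf_iter()))


def _fitch_reconstruct(tree, tip_states: dict[str, int]) -> list[tuple[str, int, int]]:
    """Minimum-change reconstruction of a binary character on a rooted
    binary tree.

    Returns the list of state changes as ``(child_branch_label,
    parent_state, child_state)``.  Ambiguous root states are resolved by
    preferring the root state that minimises changes on terminal
    branches; remaining ties take the majority state among the tips (so a
    lineage-specific gain or loss is placed on the deviating lineage's
    own stem), then state 0 (no gap).  Descending, a node takes its
    parent's state whenever its Fitch set allows it, which yields a
    minimum-change reconstruction.
    """
    sets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = frozenset((tip_states[node.taxon.label],))
        else:
            children = node.child_nodes()
            s = sets[children[0]]
            for ch in children[1:]:
                inter = s & sets[ch]
                s = inter if inter else (s | sets[ch])
            sets[node] = s

    def changes_for_root(root_state: int) -> tuple[int, list[tuple[str, int, int]]]:
        assign = {tree.seed_node: root_state}
        terminal_changes = 0
        events = []
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            parent_state = assign[node.parent_node]
            if parent_state in sets[node]:
                state = parent_state
            else:
                state = min(sets[node])  # singleton whenever parent not in set
            assign[node] = state
            if state != parent_state:
                events.append((_node_label(node), parent_state, state))
                if node.is_leaf():
                    terminal_changes += 1
        return terminal_changes, events

    root_set = sets[tree.seed_node]
    if len(root_set) == 1:
        return changes_for_root(next(iter(root_set)))[1]
    t0, ev0 = changes_for_root(0)
    t1, ev1 = changes_for_root(1)
    if t1 != t0:
        return ev1 if t1 < t0 else ev0
    n_gapped = sum(tip_states.values())
    if 2 * n_gapped > len(tip_states):
        return ev1  # tie: majority tip state at the root
    return ev0  # remaining tie: prefer an ungapped root


def fitch_parsimony_score(tree, tip_states: dict[str, int]) -> int:
    """Number of state changes in the minimum-change reconstruction."""
    return len(_fitch_reconstruct(tree, tip_states))


def infer_indel_events(
    msa: OrthogroupAlignment, phylogeny: Phylogeny
) -> list[IndelEvent]:
    """Infer indel events on the tree from the alignment's gap patterns.

    Columns are grouped into maximal intervals with a constant
    species-gap pattern; each interval's binary gap character is
    reconstructed by Fitch parsimony and one event is emitted per state
    change, on the changing branch.  Events on the same branch in
    column-adjacent intervals with the same change direction are merged
    into one spanning event.  Columns gapped in every species are
    excluded.
    """
    species = list(msa.rows)
    missing = set(species) - set(phylogeny.tip_labels)
    if missing:
        raise ConsistencyError(f"species missing from tree: {sorted(missing)}")
    sub = phylogeny.subtree_for(species)
    if not sub.is_resolved:
        sub.resolve()
    tree = sub.tree

    gap = np.array(
        [[c == GAP for c in msa.rows[sp]] for sp in species], dtype=bool
    )
    usable = ~gap.all(axis=0)

    raw_events: list[IndelEvent] = []
    col = 0
    n_cols = msa.n_columns
    while col < n_cols:
        if not usable[col]:
            col += 1
            continue
        j = col
        pattern = gap[:, col]
        while j + 1 < n_cols and usable[j + 1] and np.array_equal(gap[:, j + 1], pattern):
            j += 1
        if pattern.any():
            tip_states = {sp: int(pattern[i]) for i, sp in enumerate(species)}
            for branch, parent_state, child_state in _fitch_reconstruct(
                tree, tip_states
            ):
                raw_events.append(
                    IndelEvent(col, j + 1, branch, gap_gained=child_state == 1)
                )
        col = j + 1

    # merge column-adjacent events on the same branch with the same direction
    raw_events.sort(key=lambda e: (e.branch, e.gap_gained, e.start))
    merged: list[IndelEvent] = []
    for ev in raw_events:
        if (
            merged
            and merged[-1].branch == ev.branch
            and merged[-1].gap_gained == ev.gap_gained
            and merged[-1].end == ev.start
        ):
            merged[-1] = IndelEvent(
                merged[-1].start, ev.end, ev.branch, ev.gap_gained
            )
        else:
            merged.append(ev)
    merged.sort(key=lambda e: (e.start, e.end, e.branch))
    return merged


# ---------------------------------------------------------------------------
# Column classification and the 2x2 test


def classify_columns(
    msa: OrthogroupAlignment,
    events: list[IndelEvent],
    reference_domains: list[CoilDomain],
    reference_species: str,
) -> ColumnLabels:
    """Label alignment columns as indel-containing/-lacking and as
    inside/outside the reference species' coiled-coil.

    A column is indel-containing when at least one inferred event covers
    it.  Coiled-coil membership follows the reference residue occupying
    the column; where the reference has a gap, the column inherits the
    label of the nearest reference residue (ties toward the left
    flank).  Columns gapped in every species are excluded.
    """
    if reference_species not in msa.rows:
        raise ValueError(f"reference species {reference_species!r} not in MSA")
    ref_row = msa.rows[reference_species]
    n_cols = msa.n_columns

    # reference residue index per column; -1 where the reference is gapped
    ref_idx = np.full(n_cols, -1, dtype=int)
    k = 0
    for col, c in enumerate(ref_row):
        if c != GAP:
            ref_idx[col] = k
            k += 1

    # nearest-residue inheritance for reference-gap columns
    effective_idx = ref_idx.copy()
    non_gap_cols = np.flatnonzero(ref_idx >= 0)
    if non_gap_cols.size == 0:
        raise ValueError(
            f"reference species {reference_species!r} has no residues"
        )
    for col in np.flatnonzero(ref_idx < 0):
        left = non_gap_cols[non_gap_cols < col]
        right = non_gap_cols[non_gap_cols > col]
        if left.size and right.size:
            dl = col - left[-1]
            dr = right[0] - col
            near = left[-1] if dl <= dr else right[0]
        elif left.size:
            near = left[-1]
        else:
            near = right[0]
        effective_idx[col] = ref_idx[near]

    in_domain = np.zeros(n_cols, dtype=bool)
    for dom in reference_domains:
        in_domain |= (effective_idx >= dom.start) & (effective_idx < dom.end)

    has_indel = np.zeros(n_cols, dtype=bool)
    for ev in events:
        has_indel[ev.start : ev.end] = True

    excluded = set(all_gap_columns(msa).tolist())
    keep = np.array([c for c in range(n_cols) if c not in excluded], dtype=int)
    return ColumnLabels(
        columns=keep,
        indel_containing=has_indel[keep],
        inside_cc=in_domain[keep],
    )


def build_contingency(labels: ColumnLabels) -> ContingencyTable2x2:
    inside = labels.inside_cc
    indel = labels.indel_containing
    return ContingencyTable2x2(
        indel_in=int(np.sum(indel & inside)),
        total_in=int(np.sum(inside)),
        indel_out=int(np.sum(indel & ~inside)),
        total_out=int(np.sum(~inside)),
    )


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value by the point-probability method:
    the sum of hypergeometric probabilities (margins fixed) of all tables
    no more probable than the observed one.

    A table with any zero margin carries no information; by convention it
    returns p = 1.0 with a logged warning.
    """
    a = table.indel_in
    b = table.total_in - table.indel_in
    c = table.indel_out
    d = table.total_out - table.indel_out
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        log.warning("degenerate 2x2 table (zero margin): p = 1.0 by convention")
        return 1.0
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(min(p, 1.0))


def indel_depletion_report(
    inputs: dict[str, tuple[OrthogroupAlignment, Phylogeny, list[CoilDomain], str]],
) -> pd.DataFrame:
    """Full per-protein indel census plus a pooled "Total" row.

    ``inputs`` maps protein name to ``(msa, tree, reference_domains,
    reference_species)``.  The Total row sums the four cells over all
    proteins before a single pooled Fisher test.
    """
    tables = {}
    for name, (msa, tree, domains, ref_sp) in inputs.items():
        events = infer_indel_events(msa, tree)
        labels = classify_columns(msa, events, domains, ref_sp)
        tables[name] = build_contingency(labels)
    return depletion_report_from_tables(tables)


def depletion_report_from_tables(
    tables: dict[str, ContingencyTable2x2],
) -> pd.DataFrame:
    """Assemble the per-protein + Total depletion report from precomputed
    2x2 tables (useful when indel positions were counted elsewhere)."""
    records = []
    total = ContingencyTable2x2(0, 0, 0, 0)
    for name, tab in tables.items():
        records.append(
            {
                "protein": name,
                "indel_in": tab.indel_in,
                "total_in": tab.total_in,
                "indel_out": tab.indel_out,
                "total_out": tab.total_out,
                "p_value": fisher_exact_two_sided(tab),
            }
        )
        total = total + tab
    records.append(
        {
            "protein": "Total",
            "indel_in": total.indel_in,
            "total_in": total.total_in,
            "indel_out": total.indel_out,
            "total_out": total.total_out,
            "p_value": fisher_exact_two_sided(total),
        }
    )
    return pd.DataFrame.from_records(records)
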