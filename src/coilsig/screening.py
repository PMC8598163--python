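"""Orthogroup filtering, candidate screening and clustering.

This module implements the in-silico screen for proteins with the
synaptonemal-complex evolutionary signature: after removing paralogous
groups and thin orthogroups, rank the remainder by high divergence, low
length variation and high coiled-coil conservation, optionally
intersected with externally supplied evidence sets (single-copy status,
absence of cross-clade BLAST hits, germline expression enrichment).  A
homolog-free search over raw proteomes (longest coiled-coil length plus
protein-length windows) covers species too diverged for orthology
clustering, and a Polo-box motif scan flags the S-[S/T]-P phosphopeptide
expected in transverse-filament C-termini.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .coilscore import longest_cc_domain
from .io import ProteinRecord, ScoreProfile
from .signature import SignatureMetrics

#: search modes for the homolog-free screen: (min_domain, max_domain,
#: min_length, max_length), all bounds inclusive
SYP_SEARCH_MODES = {
    # long transverse-filament-like coiled-coil
    "syp1": (150, None, 300, 1300),
    # short accessory-protein-like coiled-coil
    "syp2": (21, 150, 175, 225),
}

POLO_BOX_MOTIF = re.compile(r"(?=(S[ST]P))")


@dataclass
class CandidateRecord:
    orthogroup_id: str
    metrics: SignatureMetrics
    flags: dict[str, bool] = field(default_factory=dict)
    rank: int | None = None

    @property
    def passed(self) -> bool:
        return all(self.flags.values())


# ---------------------------------------------------------------------------
# Orthogroup-level filters


def remove_paralogs(members: list[ProteinRecord]) -> list[ProteinRecord]:
    """Drop every member of any species represented more than once.

    Removing the whole species (not just the extra copy) avoids having to
    decide which paralog is the ortholog.
    """
    counts: dict[str, int] = {}
    for m in members:
        counts[m.species] = counts.get(m.species, 0) + 1
    return [m for m in members if counts[m.species] == 1]


def species_count_filter(
    orthogroups: dict[str, list[ProteinRecord]],
    n_possible_species: int,
    min_fraction: float = 0.5,
    min_species: int | None = None,
) -> dict[str, list[ProteinRecord]]:
    """Keep orthogroups with members from at least ``min_fraction`` of the
    possible species (paralog removal is assumed done).

    The default minimum is ``ceil(min_fraction * n_possible_species)``;
    ``min_species`` overrides it for clades where a different convention
    is wanted (e.g. 7 of 15 species).
    """
    if min_species is None:
        min_species = math.ceil(min_fraction * n_possible_species)
    return {
        og: members
        for og, members in orthogroups.items()
        if len({m.species for m in members}) >= min_species
    }


def select_coiled_coil_orthogroups(
    orthogroups: dict[str, list[ScoreProfile]],
    member_fraction: float = 0.9,
    min_domain: int = 21,
    pscore_threshold: float = 0.1,
    tolerance: int = 2,
) -> dict[str, list[ScoreProfile]]:
    """Keep orthogroups in which at least ``member_fraction`` of members
    have a coiled-coil domain of ``min_domain`` residues or longer."""
    kept = {}
    for og, profiles in orthogroups.items():
        if not profiles:
            continue
        n_ok = 0
        for prof in profiles:
            dom = longest_cc_domain(prof, pscore_threshold, tolerance)
            if dom is not None and dom.length_aa >= min_domain:
                n_ok += 1
        if n_ok / len(profiles) >= member_fraction:
            kept[og] = profiles
    return kept


# ---------------------------------------------------------------------------
# The three-metric screen


def screen_candidates(
    metrics: list[SignatureMetrics],
    min_subs: float = 0.0,
    max_cv: float = float("inf"),
    min_ccscore: float = 0.0,
    predicates: dict[str, set[str]] | None = None,
) -> list[CandidateRecord]:
    """Apply the three-metric signature thresholds plus optional ID-set
    predicates and rank the passers.

    A record passes when ``substitutions_per_site >= min_subs``,
    ``cv_length <= max_cv``, ``cc_conservation_score >= min_ccscore`` and
    its orthogroup ID is in every supplied predicate set.  Passing
    records are ranked by descending conservation score, ties broken by
    descending divergence, then lexical ID; the ranking is therefore
    independent of input order.
    """
    predicates = predicates or {}
    records = []
    for m in metrics:
        flags = {
            "min_subs": m.substitutions_per_site >= min_subs,
            "max_cv": m.cv_length <= max_cv,
            "min_ccscore": m.cc_conservation_score >= min_ccscore,
        }
        for name, id_set in predicates.items():
            flags[name] = m.orthogroup_id in id_set
        records.append(CandidateRecord(m.orthogroup_id, m, flags))
    passed = [r for r in records if r.passed]
    passed.sort(
        key=lambda r: (
            -r.metrics.cc_conservation_score,
            -r.metrics.substitutions_per_site,
            r.orthogroup_id,
        )
    )
    for i, r in enumerate(passed):
        r.rank = i + 1
    records.sort(
        key=lambda r: (r.rank if r.rank is not None else len(passed) + 1, r.orthogroup_id)
    )
    return records


def homolog_free_syp_search(
    proteins: list[tuple[ProteinRecord, ScoreProfile]],
    mode: str = "syp1",
    exclude_ids: set[str] | None = None,
    pscore_threshold: float = 0.1,
    tolerance: int = 2,
) -> list[ProteinRecord]:
    """Candidate search over raw proteins with score profiles, no
    orthology required.

    ``mode='syp1'`` keeps proteins whose longest coiled-coil is at least
    150 aa and whose length is 300-1300 aa; ``mode='syp2'`` keeps longest
    domains of 21-150 aa with lengths 175-225 aa.  Bounds are inclusive.
    ``exclude_ids`` drops proteins with external evidence against them
    (e.g. significant cross-clade BLAST hits).
    """
    if mode not in SYP_SEARCH_MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {sorted(SYP_SEARCH_MODES)}")
    min_dom, max_dom, min_len, max_len = SYP_SEARCH_MODES[mode]
    exclude_ids = exclude_ids or set()
    hits = []
    for rec, prof in proteins:
        if rec.id in exclude_ids:
            continue
        if not (min_len <= len(rec) <= max_len):
            continue
        dom = longest_cc_domain(prof, pscore_threshold, tolerance)
        if dom is None:
            continue
        if dom.length_aa < min_dom:
            continue
        if max_dom is not None and dom.length_aa > max_dom:
            continue
        hits.append(rec)
    return hits


# ---------------------------------------------------------------------------
# Display trimming, clustering, statistics


def trim_outliers(
    metrics: pd.DataFrame,
    fraction: float = 0.001,
    axes: tuple[str, ...] = ("substitutions_per_site", "cv_length"),
) -> pd.DataFrame:
    """Drop the ``ceil(fraction * n)`` largest values independently per
    axis (union of removals).  For display only; never applied before
    statistics."""
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must be in [0, 1)")
    if fraction == 0.0 or metrics.empty:
        return metrics
    n_drop = math.ceil(fraction * len(metrics))
    drop: set = set()
    for axis in axes:
        drop.update(metrics[axis].nlargest(n_drop).index)
    return metrics.drop(index=drop)


def hierarchical_cluster(
    metrics: pd.DataFrame,
    k: int = 15,
    axes: tuple[str, ...] = (
        "substitutions_per_site",
        "cv_length",
        "cc_conservation_score",
    ),
    standardize: bool = False,
) -> tuple[dict[str, int], np.ndarray]:
    """Complete-linkage agglomeration on Euclidean distances between the
    raw metric coordinates, cut to ``k`` leaves.

    The axes are used unscaled by default, matching direct dissimilarity
    of the raw coordinates; ``standardize=True`` z-scores each axis first
    (the axes have quite different ranges).  Returns (orthogroup_id ->
    leaf index in 1..k, scipy linkage matrix).
    """
    if k > len(metrics):
        raise ValueError(f"k={k} exceeds number of records ({len(metrics)})")
    pts = metrics.loc[:, list(axes)].to_numpy(dtype=float)
    if standardize:
        sd = pts.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        pts = (pts - pts.mean(axis=0)) / sd
    linkage = hierarchy.linkage(pdist(pts), method="complete")
    leaves = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    ids = (
        metrics["orthogroup_id"].tolist()
        if "orthogroup_id" in metrics.columns
        else [str(i) for i in metrics.index]
    )
    return dict(zip(ids, (int(l) for l in leaves))), linkage


def dendrogram_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialise a scipy linkage matrix as a Newick string with branch
    lengths derived from merge heights."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact distribution when ``min(n, m) <= 8`` and there are no ties;
    otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


def polo_box_scan(sequence: str) -> list[tuple[int, int]]:
    """All (possibly overlapping) S-[S/T]-P motif matches, as 1-based
    inclusive (start, end) position pairs."""
    return [
        (m.start() + 1, m.start() + 3) for m in POLO_BOX_MOTIF.finditer(sequence)
    ]
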