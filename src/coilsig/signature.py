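"""The three evolutionary-signature metrics and their building blocks.

An orthogroup's signature is the triple

* **substitutions per site** — overall mean pairwise amino-acid distance
  under a Poisson substitution model with gamma-distributed rate
  variation across sites (shape parameter 2 by default),
* **coefficient of variation of protein length** — sample SD of member
  lengths divided by their mean,
* **coiled-coil conservation score** — per alignment column, the minimum
  coiled-coil score across species; averaged over columns.

The score machinery is agnostic to what the scores mean: disorder
profiles flow through :func:`align_scores`, the coverage filter and
:func:`call_conserved_domains` identically.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConsistencyError, RangeError, SaturationError, UndefinedResultError
from .io import GAP, OrthogroupAlignment, ScoreProfile

log = logging.getLogger(__name__)


@dataclass
class AlignedScoreMatrix:
    """Per-residue scores threaded onto alignment columns.

    ``scores`` is species x columns with NaN at gap positions.
    ``retained_columns`` indexes the columns that survive coverage
    filtering (initially: all of them).
    """

    orthogroup_id: str
    species: tuple[str, ...]
    scores: np.ndarray
    retained_columns: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.retained_columns is None:
            self.retained_columns = np.arange(self.scores.shape[1])
        else:
            self.retained_columns = np.asarray(self.retained_columns, dtype=int)
        finite = self.scores[np.isfinite(self.scores)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise RangeError("aligned scores outside [0, 1]")

    @property
    def n_species(self) -> int:
        return self.scores.shape[0]

    @property
    def n_columns(self) -> int:
        return self.scores.shape[1]

    def coverage(self) -> np.ndarray:
        """Fraction of species with a residue (non-missing) per column."""
        return np.isfinite(self.scores).mean(axis=0)

    def retained(self) -> np.ndarray:
        return self.scores[:, self.retained_columns]


@dataclass(frozen=True)
class SignatureMetrics:
    orthogroup_id: str
    substitutions_per_site: float
    cv_length: float
    cc_conservation_score: float
    n_species: int


@dataclass
class ConservedDomainCall:
    """A run of alignment columns with high, consistent scores.

    ``start``/``end`` are original alignment-column coordinates (0-based
    half-open over the run's first/last retained column); ``n_columns``
    counts the retained columns in the run, which is what the minimum-
    length rule applies to.
    """

    start: int
    end: int
    columns: np.ndarray
    mean_profile: np.ndarray
    sd_profile: np.ndarray

    @property
    def n_columns(self) -> int:
        return len(self.columns)


def align_scores(
    msa: OrthogroupAlignment, profiles: dict[str, ScoreProfile]
) -> AlignedScoreMatrix:
    """Place each species' per-residue scores at its alignment columns.

    Requires a profile for every MSA species whose residues equal the
    species' ungapped row exactly; mismatches raise a
    :class:`ConsistencyError` naming the species and first offending
    position.
    """
    species = tuple(msa.rows)
    n_cols = msa.n_columns
    mat = np.full((len(species), n_cols), np.nan)
    for si, sp in enumerate(species):
        if sp not in profiles:
            raise ConsistencyError(f"no score profile for species {sp!r}")
        prof = profiles[sp]
        row = msa.rows[sp]
        ungapped = msa.ungapped(sp)
        if len(prof.residues) != len(ungapped):
            raise ConsistencyError(
                f"species {sp!r}: profile has {len(prof.residues)} residues, "
                f"alignment row has {len(ungapped)}"
            )
        for k, (a, b) in enumerate(zip(prof.residues, ungapped)):
            if a != b:
                raise ConsistencyError(
                    f"species {sp!r}: residue mismatch at ungapped position "
                    f"{k} (profile {a!r} vs alignment {b!r})"
                )
        k = 0
        for col, c in enumerate(row):
            if c != GAP:
                mat[si, col] = prof.scores[k]
                k += 1
    return AlignedScoreMatrix(msa.orthogroup_id, species, mat)


def filter_columns_by_coverage(
    matrix: AlignedScoreMatrix, min_fraction: float = 0.8
) -> AlignedScoreMatrix:
    """Drop retained columns in which fewer than ``min_fraction`` of
    species have a residue.  Order is preserved; the underlying matrix is
    shared."""
    if not (0.0 < min_fraction <= 1.0):
        raise ValueError("min_fraction must be in (0, 1]")
    cov = matrix.coverage()
    keep = [c for c in matrix.retained_columns if cov[c] >= min_fraction]
    if not keep:
        warnings.warn(
            f"orthogroup {matrix.orthogroup_id!r}: coverage filter removed "
            "every column",
            stacklevel=2,
        )
    return AlignedScoreMatrix(
        matrix.orthogroup_id, matrix.species, matrix.scores, np.array(keep, dtype=int)
    )


def cc_conservation_score(matrix: AlignedScoreMatrix) -> float:
    """Mean over retained columns of the per-column minimum score.

    Minima are taken over non-missing entries only: the coverage filter
    bounds missingness, and treating a gap as score zero would conflate
    indels with loss of coiled-coil character.
    """
    cols = matrix.retained()
    if cols.shape[1] == 0:
        raise UndefinedResultError("no retained columns")
    counts = np.isfinite(cols).sum(axis=0)
    if np.all(counts == 0):
        raise UndefinedResultError("all retained columns are fully missing")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mins = np.nanmin(cols, axis=0)
    return float(np.mean(mins[counts > 0]))


def call_conserved_domains(
    matrix: AlignedScoreMatrix,
    min_len: int = 21,
    mean_threshold: float = 0.8,
    sd_threshold: float = 0.1,
) -> list[ConservedDomainCall]:
    """Maximal runs of retained columns whose cross-species mean score
    exceeds ``mean_threshold`` and whose SD is below ``sd_threshold``,
    reported when at least ``min_len`` columns long.

    Mean and sample SD (n-1) are computed over non-missing entries; a
    column with a single residue gets SD 0.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if not (0.0 < mean_threshold < 1.0) or not (0.0 < sd_threshold < 1.0):
        raise ValueError("thresholds must be in (0, 1)")
    cols = matrix.retained()
    if cols.shape[1] == 0:
        return []
    counts = np.isfinite(cols).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(cols, axis=0)
        sds = np.nanstd(cols, axis=0, ddof=1)
    sds = np.where(counts < 2, 0.0, sds)
    ok = (counts > 0) & (means > mean_threshold) & (sds < sd_threshold)
    calls: list[ConservedDomainCall] = []
    i = 0
    while i < len(ok):
        if not ok[i]:
            i += 1
            continue
        j = i
        while j < len(ok) and ok[j]:
            j += 1
        if j - i >= min_len:
            columns = matrix.retained_columns[i:j]
            calls.append(
                ConservedDomainCall(
                    start=int(columns[0]),
                    end=int(columns[-1]) + 1,
                    columns=columns,
                    mean_profile=means[i:j],
                    sd_profile=sds[i:j],
                )
            )
        i = j
    return calls


# ---------------------------------------------------------------------------
# Divergence


def pairwise_p_distance(row_i: str, row_j: str) -> float:
    """Proportion of differing residues between two aligned rows.

    Columns gapped in either row are excluded (pairwise deletion).
    """
    if len(row_i) != len(row_j):
        raise ConsistencyError("aligned rows of unequal length")
    a = np.frombuffer(row_i.encode(), dtype="S1")
    b = np.frombuffer(row_j.encode(), dtype="S1")
    comparable = (a != b"-") & (b != b"-")
    n = int(comparable.sum())
    if n == 0:
        raise UndefinedResultError("no comparable columns")
    diff = int(np.sum(a[comparable] != b[comparable]))
    return diff / n


def gamma_poisson_distance(p: float, gamma_shape: float = 2.0) -> float:
    """Gamma-corrected Poisson amino-acid distance.

    ``d = a * ((1 - p)^(-1/a) - 1)`` with shape ``a``: substitutions per
    site under a Poisson substitution process whose site rates follow a
    gamma distribution with shape ``a``.
    """
    if p < 0.0:
        raise RangeError("p must be >= 0")
    if p >= 1.0:
        raise SaturationError("p >= 1 saturates the distance correction")
    a = gamma_shape
    return a * ((1.0 - p) ** (-1.0 / a) - 1.0)


def mean_pairwise_divergence(
    msa: OrthogroupAlignment,
    gamma_shape: float = 2.0,
    deletion: str = "pairwise",
) -> float:
    """Unweighted mean of the gamma-Poisson distance over all unordered
    pairs of alignment rows.

    ``deletion='pairwise'`` (default) excludes, per pair, only columns
    gapped in that pair; ``'complete'`` restricts every pair to columns
    without gaps in any row.  Pairs with no comparable columns are skipped
    with a warning; if every pair is skipped the mean is undefined.
    """
    rows = list(msa.rows.values())
    if len(rows) < 2:
        raise ValueError("need >= 2 rows")
    if deletion == "complete":
        keep = [
            i
            for i in range(msa.n_columns)
            if all(r[i] != GAP for r in rows)
        ]
        rows = ["".join(r[i] for i in keep) for r in rows]
        if not keep:
            raise UndefinedResultError("complete deletion removed every column")
    elif deletion != "pairwise":
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    dists = []
    for r1, r2 in itertools.combinations(rows, 2):
        try:
            p = pairwise_p_distance(r1, r2)
            dists.append(gamma_poisson_distance(p, gamma_shape))
        except (UndefinedResultError, SaturationError) as exc:
            log.warning("skipping pair: %s", exc)
    if not dists:
        raise UndefinedResultError("every pair was skipped")
    return float(np.mean(dists))


def cv_length(lengths) -> float:
    """Coefficient of variation of protein length: sample SD (n-1)
    divided by the mean."""
    lengths = np.asarray(list(lengths), dtype=float)
    if len(lengths) < 2:
        raise ValueError("need >= 2 lengths")
    if np.any(lengths <= 0):
        raise ValueError("lengths must be > 0")
    return float(np.std(lengths, ddof=1) / np.mean(lengths))


# ---------------------------------------------------------------------------
# Per-column identity


def column_identity(msa: OrthogroupAlignment, mode: str = "pairwise") -> np.ndarray:
    """Per-column identity over non-gap residues.

    ``mode='pairwise'``: mean, over all unordered pairs of non-gap
    residues, of the indicator of equality.  ``mode='consensus'``: the
    fraction of non-gap residues equal to the most frequent one.  Columns
    with fewer than two non-gap residues are NaN.
    """
    if mode not in ("pairwise", "consensus"):
        raise ValueError("mode must be 'pairwise' or 'consensus'")
    rows = list(msa.rows.values())
    out = np.full(msa.n_columns, np.nan)
    for col in range(msa.n_columns):
        residues = [r[col] for r in rows if r[col] != GAP]
        n = len(residues)
        if n < 2:
            continue
        counts = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        if mode == "consensus":
            out[col] = max(counts.values()) / n
        else:
            same_pairs = sum(k * (k - 1) // 2 for k in counts.values())
            out[col] = same_pairs / (n * (n - 1) // 2)
    return out


def sliding_window_identity(values, window: int = 10) -> np.ndarray:
    """Centred moving average ignoring NaNs, shrinking at the edges."""
    if window < 1:
        raise ValueError("window must be >= 1")
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


# ---------------------------------------------------------------------------
# Composite


def signature_metrics(
    msa: OrthogroupAlignment,
    profiles: dict[str, ScoreProfile],
    min_coverage: float = 0.8,
    gamma_shape: float = 2.0,
    deletion: str = "pairwise",
) -> SignatureMetrics:
    """Compute the three-metric signature for one orthogroup."""
    if len(msa.rows) < 2:
        raise ValueError("need >= 2 members")
    matrix = align_scores(msa, profiles)
    matrix = filter_columns_by_coverage(matrix, min_coverage)
    return SignatureMetrics(
        orthogroup_id=msa.orthogroup_id,
        substitutions_per_site=mean_pairwise_divergence(msa, gamma_shape, deletion),
        cv_length=cv_length(msa.ungapped_lengths()),
        cc_conservation_score=cc_conservation_score(matrix),
        n_species=len(msa.rows),
    )
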