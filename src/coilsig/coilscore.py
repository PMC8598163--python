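"""Per-residue coiled-coil scoring and domain extraction.

The built-in scorer is a windowed heptad-composition score: coiled-coils
are built on seven-residue repeats (positions ``a``-``g``) with
hydrophobic residues at ``a``/``d`` and charged or polar residues at
``e``/``g``.  For each residue we take the best agreement with that
pattern over every window of length ``window`` containing it and over all
seven register phases.  It is a deliberately simple stand-in for
pairwise-frequency predictors such as Paircoil2: every downstream
operation accepts externally computed profiles, so the predictor is
pluggable.

Domain extraction follows the p-score convention used in the field: a
residue belongs to a candidate coiled-coil when its p-score is below a
threshold (default 0.1, i.e. coiled-coil score above 0.9), and a domain is
the longest such stretch tolerating short interruptions (default: up to
two consecutive residues above threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ScoreProfile

#: hydrophobic residues expected at heptad positions a/d
HYDROPHOBIC = frozenset("AILMFVWYC")
#: charged or polar residues expected at heptad positions e/g
POLAR_CHARGED = frozenset("DEKRNQSTH")

W_AD = 0.7
W_EG = 0.3

#: axial rise per residue of an alpha-helical coiled-coil, nm
NM_PER_RESIDUE = 0.1485


@dataclass(frozen=True)
class CoilDomain:
    """A contiguous coiled-coil domain, 0-based half-open."""

    start: int
    end: int
    mean_score: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid domain interval [{self.start}, {self.end})")

    @property
    def length_aa(self) -> int:
        return self.end - self.start


def heptad_cc_score(
    sequence: str,
    window: int = 28,
    protein_id: str = "",
    species: str = "",
    hydrophobic=HYDROPHOBIC,
    polar=POLAR_CHARGED,
    w_ad: float = W_AD,
    w_eg: float = W_EG,
) -> ScoreProfile:
    """Score each residue for heptad-repeat character.

    For every window of ``window`` residues and every register phase, the
    window score is ``w_ad * (fraction of a/d positions with hydrophobic
    residues) + w_eg * (fraction of e/g positions with charged/polar
    residues)``.  A residue's score is the maximum over all windows that
    contain it.  Sequences shorter than ``window`` score zero everywhere.
    """
    L = len(sequence)
    if L == 0:
        raise ValueError("empty sequence")
    scores = np.zeros(L)
    if L >= window:
        hyd = np.fromiter((c in hydrophobic for c in sequence), bool, L)
        pol = np.fromiter((c in polar for c in sequence), bool, L)
        idx = np.arange(L)
        n_windows = L - window + 1
        best = np.zeros(n_windows)
        for phase in range(7):
            pos7 = (idx + phase) % 7
            is_ad = (pos7 == 0) | (pos7 == 3)
            is_eg = (pos7 == 4) | (pos7 == 6)
            frac_ad = _window_fraction(is_ad & hyd, is_ad, window)
            frac_eg = _window_fraction(is_eg & pol, is_eg, window)
            np.maximum(best, w_ad * frac_ad + w_eg * frac_eg, out=best)
        # residue score = max over windows [i-window+1, i] that exist
        for i in range(L):
            lo = max(0, i - window + 1)
            hi = min(i, n_windows - 1)
            scores[i] = best[lo : hi + 1].max()
        np.clip(scores, 0.0, 1.0, out=scores)
    return ScoreProfile(protein_id, species, sequence, scores, "coiled_coil")


def _window_fraction(hits: np.ndarray, members: np.ndarray, window: int) -> np.ndarray:
    """Per-window hit fraction among member positions (0 where no members)."""
    ch = np.concatenate(([0], np.cumsum(hits)))
    cm = np.concatenate(([0], np.cumsum(members)))
    n_hits = ch[window:] - ch[:-window]
    n_members = cm[window:] - cm[:-window]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_members > 0, n_hits / np.maximum(n_members, 1), 0.0)
    return frac


def longest_cc_domain(
    profile: ScoreProfile,
    pscore_threshold: float = 0.1,
    tolerance: int = 2,
) -> CoilDomain | None:
    """Longest coiled-coil domain of a profile, with an interruption rule.

    A residue qualifies when its p-score is below ``pscore_threshold``,
    i.e. its coiled-coil score exceeds ``1 - pscore_threshold``.  Runs of
    qualifying residues are joined across interruptions of at most
    ``tolerance`` consecutive non-qualifying residues; a longer
    interruption ends the run.  Interruption residues at a run's edges are
    trimmed.  Returns ``None`` when no residue qualifies.

    Each interruption is judged on its own length; the total number of
    interruptions in a domain is unbounded.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if profile.score_kind != "coiled_coil":
        raise ValueError(
            f"expected a coiled_coil profile, got {profile.score_kind!r}"
        )
    qualifying = np.flatnonzero(profile.scores > 1.0 - pscore_threshold)
    if qualifying.size == 0:
        return None
    runs: list[tuple[int, int]] = []
    start = prev = int(qualifying[0])
    for q in qualifying[1:]:
        q = int(q)
        if q - prev - 1 <= tolerance:
            prev = q
        else:
            runs.append((start, prev + 1))
            start = prev = q
    runs.append((start, prev + 1))
    best = max(runs, key=lambda r: r[1] - r[0])  # ties: first (leftmost) run
    s, e = best
    return CoilDomain(s, e, float(np.mean(profile.scores[s:e])))


def cc_length_nm(length_aa: int, nm_per_residue: float = NM_PER_RESIDUE) -> float:
    """Physical length of a coiled-coil of ``length_aa`` residues, in nm."""
    if length_aa < 0:
        raise ValueError("length_aa must be >= 0")
    return length_aa * nm_per_residue
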