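"""Readers and writers for the standard formats the pipeline touches.

Sequence data moves as FASTA (via Biopython), trees as Newick (via
DendroPy), per-residue score profiles as three-column TSV, and run
configuration as YAML.  No scientific computation happens here.

Coordinate conventions
----------------------
All in-memory coordinates are 0-based half-open intervals.  Anything
printed for a human (reports, motif positions) is 1-based inclusive.

The gap character is ``'-'`` only; ``'.'`` is rejected with an explicit
error rather than silently normalised.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConsistencyError, FormatError, RangeError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues legal in an unaligned protein sequence
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "X")
#: residues legal in an aligned row
ALIGNED_ALPHABET = frozenset(AMINO_ACIDS + "X-")
GAP = "-"

SCORE_KINDS = ("coiled_coil", "disorder", "raw_pscore")


def default_species_parser(header: str) -> str:
    """Species from a FASTA header: token before the first ``'|'``, else the
    whole first whitespace-delimited token.

    The convention is configurable because public protein sets carry no
    fixed header grammar; pass any ``str -> str`` callable instead.
    """
    token = header.split()[0]
    if "|" in token:
        return token.split("|", 1)[0]
    return token


@dataclass(frozen=True)
class ProteinRecord:
    """One unaligned protein sequence with its species of origin."""

    id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r}: illegal residue characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class OrthogroupAlignment:
    """A multiple sequence alignment of one orthologous protein family.

    ``rows`` maps species name to its aligned row (residues plus ``'-'``),
    in input order.  Each species appears once; paralog handling happens
    upstream of alignment (see :mod:`coilsig.screening`).
    """

    orthogroup_id: str
    rows: dict[str, str]
    ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise FormatError(
                f"orthogroup {self.orthogroup_id!r}: need >= 2 aligned rows"
            )
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise FormatError(
                f"orthogroup {self.orthogroup_id!r}: aligned rows have "
                f"unequal lengths {sorted(lengths)}"
            )
        for sp, row in self.rows.items():
            bad = set(row) - ALIGNED_ALPHABET
            if bad:
                raise FormatError(
                    f"orthogroup {self.orthogroup_id!r}, species {sp!r}: "
                    f"illegal characters {sorted(bad)} (note '.' gaps are not accepted)"
                )

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def species(self) -> list[str]:
        return list(self.rows)

    def ungapped(self, species: str) -> str:
        return self.rows[species].replace(GAP, "")

    def ungapped_lengths(self) -> list[int]:
        return [len(self.ungapped(sp)) for sp in self.rows]


@dataclass
class Phylogeny:
    """A rooted tree with unique tip labels, wrapping a DendroPy tree.

    Polytomies are accepted on read and flagged; they must be resolved
    (deterministically, see :meth:`resolve`) before parsimony use.
    """

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    @property
    def n_internal(self) -> int:
        return sum(1 for nd in self.tree.preorder_node_iter() if not nd.is_leaf())

    @property
    def is_resolved(self) -> bool:
        """True when every internal node (including the root) is binary."""
        for nd in self.tree.preorder_node_iter():
            if not nd.is_leaf() and len(nd.child_nodes()) != 2:
                return False
        return True

    def resolve(self) -> "Phylogeny":
        """Resolve polytomies deterministically, in place, and return self.

        Each polytomous node is ladderised in input order: its first two
        children are joined under a new zero-length branch, repeatedly,
        until the node is binary.  Deterministic by construction.
        """
        for nd in list(self.tree.preorder_node_iter()):
            while not nd.is_leaf() and len(nd.child_nodes()) > 2:
                a, b = nd.child_nodes()[0], nd.child_nodes()[1]
                nd.remove_child(a)
                nd.remove_child(b)
                joint = dendropy.Node(edge_length=0.0)
                joint.add_child(a)
                joint.add_child(b)
                nd.insert_child(0, joint)
        return self

    def subtree_for(self, species: Iterable[str]) -> "Phylogeny":
        """Copy of the tree pruned to ``species``, unifurcations suppressed."""
        wanted = set(species)
        missing = wanted - set(self.tip_labels)
        if missing:
            raise ConsistencyError(
                f"species absent from tree: {sorted(missing)}"
            )
        sub = self.tree.extract_tree_with_taxa_labels(labels=wanted)
        sub.is_rooted = True
        return Phylogeny(sub)

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise FormatError(f"invalid Newick: {exc}") from exc
        tree.is_rooted = True
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise FormatError("duplicate tip labels in tree")
        return cls(tree)


@dataclass
class ScoreProfile:
    """Per-residue scores in [0, 1] for one protein.

    ``score_kind`` is ``coiled_coil`` (high = likely coiled-coil, i.e.
    1 - Paircoil2-style p-score), ``disorder`` (high = likely disordered),
    or ``raw_pscore`` (Paircoil2 convention, low = coiled-coil).  The
    analysis modules expect ``coiled_coil`` or ``disorder``; use
    :meth:`to_coiled_coil` to convert a raw profile.
    """

    protein_id: str
    species: str
    residues: str
    scores: np.ndarray
    score_kind: str = "coiled_coil"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.score_kind not in SCORE_KINDS:
            raise ValueError(f"unknown score_kind {self.score_kind!r}")
        if len(self.scores) != len(self.residues):
            raise ConsistencyError(
                f"profile {self.protein_id!r}: {len(self.scores)} scores for "
                f"{len(self.residues)} residues"
            )
        if self.scores.size and (
            np.min(self.scores) < 0.0 or np.max(self.scores) > 1.0
        ):
            raise RangeError(
                f"profile {self.protein_id!r}: scores outside [0, 1]"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def to_coiled_coil(self) -> "ScoreProfile":
        """Convert a raw p-score profile (low = coiled-coil) to a
        coiled-coil score profile (1 - pscore).  A no-op otherwise."""
        if self.score_kind != "raw_pscore":
            return self
        return ScoreProfile(
            self.protein_id, self.species, self.residues,
            1.0 - self.scores, "coiled_coil",
        )


# ---------------------------------------------------------------------------
# FASTA


def _parse_fasta_records(
    handle, species_parser: Callable[[str], str]
) -> list[tuple[str, str, str]]:
    out = []
    for rec in SeqIO.parse(handle, "fasta"):
        header = rec.description or rec.id
        out.append((rec.id, species_parser(header), str(rec.seq).upper()))
    return out


def read_fasta(
    path,
    aligned: bool = False,
    species_parser: Callable[[str], str] = default_species_parser,
    orthogroup_id: str | None = None,
):
    """Read a protein FASTA file.

    With ``aligned=False`` returns a list of :class:`ProteinRecord` in file
    order.  With ``aligned=True`` returns an :class:`OrthogroupAlignment`
    (one row per species; duplicated species are a format error, remove
    paralogs first).
    """
    path = Path(path)
    with open(path) as fh:
        raw = _parse_fasta_records(fh, species_parser)
    if not raw:
        raise FormatError(f"{path}: no FASTA records")
    if not aligned:
        records = []
        for rid, sp, seq in raw:
            if GAP in seq or "." in seq:
                raise FormatError(
                    f"{path}, record {rid!r}: gap characters in unaligned FASTA"
                )
            records.append(ProteinRecord(rid, sp, seq))
        return records
    lengths = {len(seq) for _, _, seq in raw}
    if len(lengths) != 1:
        raise FormatError(
            f"{path}: aligned sequences have unequal lengths {sorted(lengths)}"
        )
    rows: dict[str, str] = {}
    ids: dict[str, str] = {}
    for rid, sp, seq in raw:
        if sp in rows:
            raise FormatError(
                f"{path}: species {sp!r} appears more than once in alignment"
            )
        rows[sp] = seq
        ids[sp] = rid
    return OrthogroupAlignment(orthogroup_id or path.stem, rows, ids)


def write_fasta(records, path, line_width: int = 60) -> None:
    """Write :class:`ProteinRecord` objects or an
    :class:`OrthogroupAlignment` as FASTA.

    ``line_width`` controls wrapping (0 = single line); content round-trips
    byte-for-byte modulo that wrapping.
    """
    if isinstance(records, OrthogroupAlignment):
        items = [
            (records.ids.get(sp, sp), records.rows[sp]) for sp in records.rows
        ]
    else:
        items = [(r.id, r.sequence) for r in records]
    with open(path, "w") as fh:
        for rid, seq in items:
            fh.write(f">{rid}\n")
            if line_width <= 0:
                fh.write(seq + "\n")
            else:
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")


def fasta_string(records, line_width: int = 60) -> str:
    """FASTA serialisation as a string (used for determinism checks)."""
    buf = _io.StringIO()
    if isinstance(records, OrthogroupAlignment):
        items = [
            (records.ids.get(sp, sp), records.rows[sp]) for sp in records.rows
        ]
    else:
        items = [(r.id, r.sequence) for r in records]
    for rid, seq in items:
        buf.write(f">{rid}\n")
        if line_width <= 0:
            buf.write(seq + "\n")
        else:
            for i in range(0, len(seq), line_width):
                buf.write(seq[i : i + line_width] + "\n")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Newick


def read_newick(path) -> Phylogeny:
    """Read a rooted tree from a Newick file."""
    with open(path) as fh:
        return Phylogeny.from_newick(fh.read())


def write_newick(phylogeny: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(phylogeny.newick() + "\n")


# ---------------------------------------------------------------------------
# Score-profile TSV

PROFILE_COLUMNS = ("position", "residue", "score")


def read_score_profile(
    path,
    score_kind: str = "coiled_coil",
    protein_id: str | None = None,
    species: str = "",
) -> ScoreProfile:
    """Read a per-residue score profile from TSV.

    Expected columns: ``position`` (1-based, contiguous from 1),
    ``residue``, ``score`` (in [0, 1]).  With ``score_kind='raw_pscore'``
    (Paircoil2 convention, low = coiled-coil) the stored scores are
    converted to coiled-coil scores as ``1 - pscore``.
    """
    path = Path(path)
    if score_kind not in SCORE_KINDS:
        raise ValueError(f"unknown score_kind {score_kind!r}")
    df = pd.read_csv(path, sep="\t")
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    pos = df["position"].to_numpy()
    if len(pos) == 0:
        raise FormatError(f"{path}: empty profile")
    expected = np.arange(1, len(pos) + 1)
    if not np.array_equal(pos, expected):
        first_bad = int(expected[pos != expected][0])
        raise FormatError(
            f"{path}: positions must be contiguous from 1 "
            f"(first gap/disorder at expected position {first_bad})"
        )
    scores = df["score"].to_numpy(dtype=float)
    if np.min(scores) < 0.0 or np.max(scores) > 1.0:
        raise RangeError(f"{path}: score outside [0, 1]")
    residues = "".join(df["residue"].astype(str))
    profile = ScoreProfile(
        protein_id or path.stem, species, residues, scores, score_kind
    )
    return profile.to_coiled_coil()


def write_score_profile(profile: ScoreProfile, path) -> None:
    df = pd.DataFrame(
        {
            "position": np.arange(1, len(profile) + 1),
            "residue": list(profile.residues),
            "score": profile.scores,
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Config


def load_config(path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
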