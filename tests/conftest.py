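import numpy as np
import pytest

from coilsig import OrthogroupAlignment, Phylogeny, ScoreProfile


@pytest.fixture
def quartet_tree() -> Phylogeny:
    return Phylogeny.from_newick("((A,B),(C,D));")


@pytest.fixture
def make_msa():
    def _make(rows: dict[str, str], og_id: str = "og") -> OrthogroupAlignment:
        return OrthogroupAlignment(og_id, rows)

    return _make


@pytest.fixture
def make_profile():
    def _make(scores, residues: str | None = None, kind: str = "coiled_coil",
              protein_id: str = "p", species: str = "sp") -> ScoreProfile:
        scores = np.asarray(scores, dtype=float)
        if residues is None:
            residues = "A" * len(scores)
        return ScoreProfile(protein_id, species, residues, scores, kind)

    return _make
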