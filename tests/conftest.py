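import numpy as np
import pytest

from famimpute.pedigree_io import Individual, Pedigree, compute_phi


def make_random_pedigree(rng: np.random.Generator, n_members: int) -> Pedigree:
    """Random non-inbred pedigree: each non-founder has one existing parent
    and one freshly created founder spouse, so no loops of shared ancestry
    form and the relationship matrix stays a valid non-inbred one."""
    inds = [Individual("i1", "famA"), Individual("i2", "famA")]
    k = 2
    while len(inds) < n_members:
        parent = inds[rng.integers(len(inds))]
        k += 1
        spouse = Individual(f"i{k}", "famA")
        inds.append(spouse)
        if len(inds) >= n_members:
            break
        k += 1
        inds.append(Individual(f"i{k}", "famA", father=parent.iid, mother=spouse.iid))
    return Pedigree(inds)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def nuclear_pedigree():
    """One nuclear family: parents f, m and full sibs c1, c2."""
    return Pedigree(
        [
            Individual("f", "fam1"),
            Individual("m", "fam1"),
            Individual("c1", "fam1", "f", "m"),
            Individual("c2", "fam1", "f", "m"),
        ]
    )


@pytest.fixture
def nuclear_phi(nuclear_pedigree):
    return compute_phi(nuclear_pedigree)


@pytest.fixture
def trio_fam_file(tmp_path):
    path = tmp_path / "trio.fam"
    path.write_text("fam1 F 0 0 1 -9\nfam1 M 0 0 2 -9\nfam1 C F M 1 -9\n")
    return path
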