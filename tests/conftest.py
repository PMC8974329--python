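import pytest

from famlong import lifetables, synthetic
from famlong.pedigree import Individual, Pedigree

GOMPERTZ_A, GOMPERTZ_B = 1e-4, 0.085


@pytest.fixture(scope="session")
def gompertz_table():
    return lifetables.make_gompertz_table(GOMPERTZ_A, GOMPERTZ_B, "female",
                                          (1900, 1930), 110)


@pytest.fixture(scope="session")
def cohort_table():
    return lifetables.default_cohort_table()


@pytest.fixture(scope="session")
def small_pedigrees():
    """Ten default-structure families (deterministic)."""
    return synthetic.simulate_pedigrees(synthetic.SimConfig(n_families=10,
                                                            seed=42))


@pytest.fixture
def trio():
    inds = {
        "F": Individual("F", "fam1", None, None, "male"),
        "M": Individual("M", "fam1", None, None, "female"),
        "C": Individual("C", "fam1", "F", "M", "female"),
    }
    return Pedigree("fam1", inds)


def nuclear_family(n_children: int, family_id: str = "fam") -> Pedigree:
    inds = {
        "dad": Individual("dad", family_id, None, None, "male"),
        "mom": Individual("mom", family_id, None, None, "female"),
    }
    for k in range(n_children):
        inds[f"c{k}"] = Individual(f"c{k}", family_id, "dad", "mom",
                                   "male" if k % 2 else "female")
    return Pedigree(family_id, inds)


def three_generation_pedigree() -> Pedigree:
    """Grandparents, two children with spouses, grandchildren incl. half-sibs."""
    I = Individual
    inds = {}
    for pid, fa, mo, sex in [
        ("gpa", None, None, "male"), ("gma", None, None, "female"),
        ("s1", "gpa", "gma", "male"), ("s2", "gpa", "gma", "female"),
        ("w1", None, None, "female"), ("w1b", None, None, "female"),
        ("h2", None, None, "male"),
        ("k1", "s1", "w1", "male"), ("k2", "s1", "w1", "female"),
        ("k3", "s1", "w1b", "male"),                     # half-sib of k1/k2
        ("k4", "h2", "s2", "female"),                    # cousin of k1..k3
    ]:
        inds[pid] = I(pid, "fam3g", fa, mo, sex)
    return Pedigree("fam3g", inds)

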