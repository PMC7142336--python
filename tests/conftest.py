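import numpy as np
import pytest

from hmmdbp import FeatureSpec, HmmProfile, SyntheticSpec, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_profile(rng):
    """A 40 x 20 profile of uniform values in [0, 1]."""
    return HmmProfile("rand01", rng.uniform(0.0, 1.0, size=(40, 20)))


def profile_with_columns(col_values: dict[int, list[float]], fill: float = 0.5):
    """Profile whose listed columns take the given values, others constant."""
    L = len(next(iter(col_values.values())))
    M = np.full((L, 20), fill)
    for j, vals in col_values.items():
        M[:, j] = vals
    return HmmProfile("cols", M)


@pytest.fixture(scope="session")
def signal_dataset():
    """A clearly separable synthetic dataset reused by slower tests."""
    spec = SyntheticSpec(
        n_pos=60, n_neg=60, length_range=(50, 120), effect_size=1.5, seed=7
    )
    return make_dataset(spec, FeatureSpec(max_lag=3))


# A hand-written 5-residue .hhm document with mixed integer scores.  Column
# 0 of each block carries a distinctive score; remaining columns are 1000
# except where noted.  Used for parser fixtures and the hand-computed table.
FIVE_RESIDUE_SCORES = [
    [0, 1000, 2000, 3000, 500] + [1000] * 15,
    [100, 200, 300, 400, 500] + [2000] * 15,
    [1000] * 20,
    [4000, 3500, 250, 750, 1250] + [500] * 15,
    [999, 1, 123, 4567, 89] + [3000] * 15,
]


def hhm_document(score_rows, residues="MKLVA", name="fix5", star_at=None):
    """Render residue blocks into a minimal valid .hhm document.

    ``star_at`` optionally replaces one (row, col) score with ``*``.
    """
    lines = [
        "HHsearch 1.5",
        f"NAME  {name}",
        f"LENG  {len(score_rows)} match states, {len(score_rows)} columns in multiple alignment",
        "#",
        "NULL   " + "\t".join(["3000"] * 20),
        "HMM    A\tC\tD\tE\tF\tG\tH\tI\tK\tL\tM\tN\tP\tQ\tR\tS\tT\tV\tW\tY",
        "       M->M\tM->I\tM->D\tI->M\tI->I\tD->M\tD->D\tNeff\tNeff_I\tNeff_D",
        "       0\t*\t*\t0\t*\t0\t*\t*\t*\t*",
    ]
    for i, row in enumerate(score_rows):
        tokens = [str(s) for s in row]
        if star_at is not None and star_at[0] == i:
            tokens[star_at[1]] = "*"
        lines.append(f"{residues[i]} {i + 1}\t" + "\t".join(tokens) + f"\t{i + 1}")
        lines.append("       0\t*\t*\t*\t*\t*\t*\t1000\t0\t0")
        lines.append("")
    lines.append("//")
    return "\n".join(lines) + "\n"
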