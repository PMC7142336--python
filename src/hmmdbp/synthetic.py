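"""Synthetic labeled profile HMMs with controllable class signal.

The generator emulates the statistical structure that the AAC/ACT/CCT
descriptors detect, so every pipeline stage can be exercised without any
sequence database or HHblits run:

* **AAC signal** — selected columns get a mean shift in the positive class;
* **ACT signal** — selected columns carry first-order autoregressive noise
  (lag-1 autocorrelation) in the positive class, iid noise otherwise;
* **CCT signal** — selected ordered column pairs (j, k) are coupled in the
  positive class: column k partially copies column j shifted by a lag.

Values are generated directly in the transformed [0, 1] probability space
(what the features consume) and inverse-mapped to integer scores only when
profiles are written to disk.  Per-column baseline means are drawn once per
run so columns are non-exchangeable, mimicking amino-acid composition bias;
each protein additionally gets its own per-column random offset so the two
classes overlap rather than separating trivially.  ``effect_size = 0``
makes the class distributions identical (a null dataset); out-of-range
values are clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .data import LabeledDataset
from .features import FeatureSpec, featurize_profiles
from .profile_io import RESIDUE_ORDER, HmmProfile, write_hhm


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults mirror the benchmark this generator stands in for: 525
    positives and 550 negatives, sequence lengths drawn uniformly from
    [50, 300] (the benchmark filters out sequences under 50 residues).
    ``effect_size`` scales all three planted signals; 1.0 gives a clearly
    learnable but not saturated problem.
    """

    n_pos: int = 525
    n_neg: int = 550
    length_range: tuple[int, int] = (50, 300)
    mean_shift_columns: tuple[int, ...] = (0, 3, 8, 12)
    ar_columns: tuple[int, ...] = (1, 6)
    coupled_pairs: tuple[tuple[int, int], ...] = ((2, 7),)
    coupling_lag: int = 1
    effect_size: float = 1.0
    noise_sd: float = 0.08
    protein_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid length_range {self.length_range}")
        cols = set(self.mean_shift_columns) | set(self.ar_columns)
        for j, k in self.coupled_pairs:
            cols |= {j, k}
            if j == k:
                raise ValueError("coupled pairs must join distinct columns")
        if any(not 0 <= c < 20 for c in cols):
            raise ValueError("all referenced column indices must lie in 0..19")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.coupling_lag < 1:
            raise ValueError("coupling_lag must be >= 1")


# Signal-strength coefficients per unit effect_size.  The mean shift is
# calibrated against protein_sd (per-protein composition scatter), the AR
# coefficient and coupling weight against noise_sd (residue-level scatter).
_MEAN_SHIFT = 0.08
_AR_COEF = 0.35
_COUPLING = 0.5


def generate_profiles(
    spec: SyntheticSpec,
) -> tuple[list[HmmProfile], dict[str, int]]:
    """Draw ``n_pos + n_neg`` labeled profiles, reproducibly from the seed."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    base_means = rng.uniform(0.25, 0.6, size=20)
    phi = min(_AR_COEF * spec.effect_size, 0.95)
    beta = min(_COUPLING * spec.effect_size, 1.0)
    shift = _MEAN_SHIFT * spec.effect_size
    letters = np.array(RESIDUE_ORDER)

    profiles: list[HmmProfile] = []
    labels: dict[str, int] = {}
    n_total = spec.n_pos + spec.n_neg
    width = max(4, len(str(n_total)))
    for idx in range(n_total):
        label = 1 if idx < spec.n_pos else 0
        L = int(rng.integers(lo, hi + 1))
        offsets = rng.normal(0.0, spec.protein_sd, size=20)
        M = base_means + offsets + rng.normal(0.0, spec.noise_sd, size=(L, 20))
        if label == 1:
            M[:, list(spec.mean_shift_columns)] += shift
            for j in spec.ar_columns:
                # AR(1) noise with the same marginal sd as the iid baseline
                innov = rng.normal(
                    0.0, spec.noise_sd * np.sqrt(1.0 - phi**2), size=L
                )
                e = np.empty(L)
                e[0] = rng.normal(0.0, spec.noise_sd)
                for i in range(1, L):
                    e[i] = phi * e[i - 1] + innov[i]
                M[:, j] = base_means[j] + offsets[j] + e
            g = spec.coupling_lag
            if L > g:
                for j, k in spec.coupled_pairs:
                    src = M[: L - g, j] - M[:, j].mean()
                    M[g:, k] = (
                        base_means[k]
                        + offsets[k]
                        + beta * src
                        + rng.normal(0.0, spec.noise_sd, size=L - g)
                    )
        # at effect 0 the shift, phi and beta all vanish and the redrawn
        # positive-class columns keep the baseline marginal law, so the two
        # class distributions coincide exactly
        M = np.clip(M, 0.0, 1.0)
        seq = "".join(rng.choice(letters, size=L))
        pid = f"syn{idx:0{width}d}"
        profiles.append(HmmProfile(sequence_id=pid, matrix=M, sequence=seq))
        labels[pid] = label
    return profiles, labels


def emit_fixture_dir(
    profiles: Sequence[HmmProfile],
    labels: dict[str, int],
    directory: Union[str, Path],
) -> Path:
    """Write one ``.hhm`` per profile plus a two-column label file.

    Refuses to overwrite an existing profile file (id collision)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for p in profiles:
        target = directory / f"{p.sequence_id}.hhm"
        if target.exists():
            raise FileExistsError(f"profile file already exists: {target}")
        write_hhm(p, target)
    with open(directory / "labels.tsv", "w") as fh:
        for p in profiles:
            fh.write(f"{p.sequence_id}\t{labels[p.sequence_id]}\n")
    return directory


def make_dataset(
    spec: SyntheticSpec, feature_spec: FeatureSpec | None = None
) -> LabeledDataset:
    """Generate profiles and featurize them in one step."""
    profiles, labels = generate_profiles(spec)
    ds = featurize_profiles(profiles, labels, feature_spec)
    ds.provenance["synthetic_spec"] = spec.__dict__.copy()
    return ds
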