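"""Synthetic study-data generators.

Every analysis stage in the package can be exercised without the
access-restricted imaging cohorts it was designed for: this module
generates (i) MZ/DZ twin cohorts whose regional volumes follow the AE
variance-components model with known heritability, (ii) repeated-
measurement tables with a known expected consistency ICC, (iii) paired
cross-version volume columns with a known correlation and scale offset,
and (iv) paired label images with geometrically controlled overlap.

Randomness is hierarchical: one master seed spawns independent
substreams per purpose and per region, so adding a region to a cohort
spec does not perturb the draws of existing regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import LabelVolume, MeasurementTable, Pedigree
from .refdata import DEFAULT_REGION_PARAMS

_TWO_PHI = {"MZ": 1.0, "DZ": 0.5}


@dataclass
class CohortSpec:
    """Generative description of a twin cohort.

    Defaults follow the design of a large young-adult twin imaging
    study: 132 MZ + 232 DZ pairs, ages ~N(22.65, 2.73^2) years shared
    within a pair, and per-region (mean, SD, true h^2) at hippocampal-
    subfield scale.
    """

    n_mz_pairs: int = 132
    n_dz_pairs: int = 232
    region_params: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REGION_PARAMS)
    )
    covariate_effects: tuple[float, float, float] = (0.0, 0.0, 0.0)
    age_distribution: tuple[float, float] = (22.65, 2.73)
    female_fraction: float = 0.64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mz_pairs < 0 or self.n_dz_pairs < 0:
            raise ValueError("pair counts must be non-negative")
        if self.n_mz_pairs + self.n_dz_pairs < 1:
            raise ValueError("need at least one twin pair")
        for region, (mean, sd, h2) in self.region_params.items():
            if sd <= 0:
                raise ValueError(f"{region}: SD must be positive")
            if not 0.0 <= h2 <= 1.0:
                raise ValueError(f"{region}: h2 must lie in [0, 1]")
        if self.age_distribution[1] < 0:
            raise ValueError("age SD must be non-negative")


@dataclass
class RetestSpec:
    """Target two-session consistency ICC for a test-retest table."""

    target_icc: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_icc < 1.0:
            raise ValueError("target_icc must lie strictly inside (0, 1)")


def _cohort_frame(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Pedigree skeleton: ids, zygosity, shared pair age, sexes."""
    rows = []
    fam = 0
    for zyg, n_pairs in (("MZ", spec.n_mz_pairs), ("DZ", spec.n_dz_pairs)):
        ages = rng.normal(*spec.age_distribution, size=n_pairs)
        ages = np.clip(ages, 0.0, None)
        for p in range(n_pairs):
            fam += 1
            fam_id = f"fam{fam:04d}"
            if zyg == "MZ":
                s = "F" if rng.random() < spec.female_fraction else "M"
                sexes = (s, s)
            else:
                sexes = tuple(
                    "F" if rng.random() < spec.female_fraction else "M"
                    for _ in range(2)
                )
            for k in range(2):
                rows.append(
                    (f"{fam_id}_{k + 1}", fam_id, zyg, sexes[k], float(ages[p]))
                )
    return pd.DataFrame(
        rows, columns=["individual_id", "family_id", "zygosity", "sex", "age"]
    )


def simulate_twin_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, Pedigree]:
    """Draw a twin cohort under the AE model.

    For each region and family the pair phenotype is bivariate normal
    with mean mu + beta_age*age + beta_sex*sex + beta_axs*age*sex,
    common variance sigma_p^2 = SD^2 and within-pair covariance
    2*Phi*h2*sigma_p^2 (2*Phi = 1 for MZ, 0.5 for DZ).  The genetic
    part is drawn as a shared component of variance 2*Phi*h2*sigma_p^2
    plus an individual component carrying the remainder of the genetic
    variance, plus independent residual noise.

    Returns
    -------
    (volumes, pedigree)
        ``volumes``: subjects x regions DataFrame indexed by
        individual_id; ``pedigree``: validated twin Pedigree.
    """
    root = np.random.SeedSequence(spec.seed)
    # substream 0: cohort structure (ages, sexes) shared by all regions
    struct_ss, regions_ss = root.spawn(2)
    ped_df = _cohort_frame(spec, np.random.default_rng(struct_ss))
    pedigree = Pedigree(ped_df)
    df = pedigree.table

    two_phi = df.groupby("family_id", sort=False)["zygosity"].first().map(_TWO_PHI)
    n_fam = len(two_phi)
    two_phi_arr = two_phi.to_numpy(float)

    sex_ind = (df["sex"] == "M").to_numpy(float).reshape(n_fam, 2)
    ages = df["age"].to_numpy(float).reshape(n_fam, 2)
    b_age, b_sex, b_axs = spec.covariate_effects

    region_streams = regions_ss.spawn(len(spec.region_params))
    cols = {}
    for ss, (region, (mean, sd, h2)) in zip(
        region_streams, spec.region_params.items()
    ):
        rng = np.random.default_rng(ss)
        sp2 = sd * sd
        shared_var = two_phi_arr * h2 * sp2            # per family
        indiv_var = (1.0 - two_phi_arr) * h2 * sp2     # genetic remainder
        env_var = (1.0 - h2) * sp2
        shared = rng.normal(0.0, 1.0, size=n_fam) * np.sqrt(shared_var)
        indiv = rng.normal(0.0, 1.0, size=(n_fam, 2)) * np.sqrt(
            indiv_var
        )[:, None]
        env = rng.normal(0.0, np.sqrt(env_var), size=(n_fam, 2))
        values = (
            mean
            + b_age * ages
            + b_sex * sex_ind
            + b_axs * ages * sex_ind
            + shared[:, None]
            + indiv
            + env
        )
        cols[region] = values.ravel()
    volumes = pd.DataFrame(
        cols, index=pd.Index(df["individual_id"], name="individual_id")
    )
    return volumes, pedigree


def simulate_retest(
    base_volumes: np.ndarray | pd.Series, spec: RetestSpec,
    region_name: str = "region",
) -> MeasurementTable:
    """Two-session measurement table with a known expected ICC.

    Each session equals the latent base volume plus independent
    Gaussian error of variance

        sigma_err^2 = 2 * sigma_base^2 * (1 - t) / t,   t = target_icc,

    chosen so that the expected two-column consistency ICC (Cronbach's
    alpha, the average-measures statistic this package computes) equals
    the target: alpha = 2 sigma_b^2 / (2 sigma_b^2 + sigma_err^2) = t.
    """
    base = np.asarray(base_volumes, dtype=float)
    var_base = float(np.var(base, ddof=1))
    if not var_base > 0:
        raise ValueError("base volumes must have nonzero variance")
    t = spec.target_icc
    sigma_err = np.sqrt(2.0 * var_base * (1.0 - t) / t)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    noise = rng.normal(0.0, sigma_err, size=(base.size, 2))
    values = base[:, None] + noise
    if isinstance(base_volumes, pd.Series):
        subject_ids = [str(s) for s in base_volumes.index]
    else:
        subject_ids = [f"s{i:04d}" for i in range(base.size)]
    return MeasurementTable(
        region_name=region_name,
        rater_labels=["baseline", "followup"],
        values=values,
        subject_ids=subject_ids,
    )


def simulate_version_pair(
    base_volumes: np.ndarray | pd.Series,
    correlation: float,
    scale: float = 1.0,
    seed: int = 0,
    region_name: str = "region",
) -> MeasurementTable:
    """Cross-version volume pair with a set correlation and scale offset.

    The second column has Pearson correlation ``correlation`` with the
    first and is multiplied by ``scale``.  The consistency ICC is
    invariant to an additive offset but not to a multiplicative one, so
    it reproduces the correlation only at scale = 1.
    """
    if not -1.0 <= correlation <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    if scale <= 0:
        raise ValueError("scale must be positive")
    base = np.asarray(base_volumes, dtype=float)
    mu = float(np.mean(base))
    sd = float(np.std(base, ddof=1))
    if not sd > 0:
        raise ValueError("base volumes must have nonzero variance")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    noise = rng.normal(0.0, 1.0, size=base.size)
    second = mu + correlation * (base - mu) + np.sqrt(1 - correlation**2) * sd * noise
    values = np.column_stack([base, scale * second])
    if isinstance(base_volumes, pd.Series):
        subject_ids = [str(s) for s in base_volumes.index]
    else:
        subject_ids = [f"s{i:04d}" for i in range(base.size)]
    return MeasurementTable(
        region_name=region_name,
        rater_labels=["v6.0", "v5.3"],
        values=values,
        subject_ids=subject_ids,
    )


def _ellipsoid_mask(
    grid_shape: tuple[int, int, int],
    center: np.ndarray,
    semi_axes: np.ndarray,
) -> np.ndarray:
    idx = np.indices(grid_shape, dtype=float)
    d2 = sum(
        ((idx[k] - center[k]) / semi_axes[k]) ** 2 for k in range(3)
    )
    return d2 <= 1.0


def simulate_label_pair(
    shape: tuple[float, float, float],
    offset: tuple[int, int, int] = (0, 0, 0),
    grid: tuple[int, int, int] = (32, 32, 32),
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    label: int = 1,
    label_name: str = "region",
    seed: int = 0,
) -> tuple[LabelVolume, LabelVolume]:
    """Two single-label ellipsoid masks, the second rigidly translated.

    ``shape`` gives the ellipsoid semi-axes in voxels; the expected DSC
    is computable by voxel enumeration.  Both masks must fit inside the
    grid after the offset.
    """
    semi = np.asarray(shape, dtype=float)
    grid_shape = tuple(int(g) for g in grid)
    off = np.asarray(offset, dtype=int)
    if np.any(semi <= 0):
        raise ValueError("semi-axes must be positive")
    # mask B is an exact voxel translate of mask A (integer offset), so
    # brute-force enumeration of the overlap is well defined
    center = (np.asarray(grid_shape) - 1) / 2.0
    center_b = center + off
    for c in (center, center_b):
        if np.any(c - semi < -0.5) or np.any(c + semi > np.asarray(grid_shape) - 0.5):
            raise ValueError("ellipsoid does not fit within the grid after offset")
    mask_a = _ellipsoid_mask(grid_shape, center, semi)
    mask_b = _ellipsoid_mask(grid_shape, center_b, semi)
    label_map = {int(label): label_name}
    vol_a = LabelVolume(
        grid=mask_a.astype(np.int16) * label, voxel_size=voxel_size,
        label_map=label_map,
    )
    vol_b = LabelVolume(
        grid=mask_b.astype(np.int16) * label, voxel_size=voxel_size,
        label_map=label_map,
    )
    return vol_a, vol_b
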