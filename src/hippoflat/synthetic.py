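"""Synthetic phantoms and cohorts with known ground truth.

Two generators make the whole pipeline testable without patient data:

* **Volumetric phantoms** — sheet-like gray-matter geometries (flat slab,
  extruded cylindrical shell, folded C-sheet) of known thickness, bounded by
  white matter on one side and CSF on the other, optionally partitioned into
  up to 7 subregion bands along the sheet.  These emulate the segmented
  substrate of a high-resolution medial-temporal acquisition (in-plane
  ~0.39 mm, 3 mm slices) while recording true geometric thickness per
  location.

* **Synthetic cohorts** — subject tables with the demographic and genetic
  structure of a 58-patient Alzheimer's disease sample (two education groups,
  APOE genotype and family-history counts fixed exactly, three derived risk
  levels) and per-subregion thickness simulated as
  ``base + slope(risk, subregion) * (education - mean) + noise``.
  Slopes default to values calibrated so that the education-thickness Pearson
  correlations within risk strata match configured targets; the noise has a
  shared across-subregion component so the correlation of the *mean*
  thickness also matches its target (independent noise would overshoot it).

Edge voxels of a finite sheet see a spuriously close non-gray boundary;
phantoms therefore carry unlabeled plain-GM "flank" margins around the
banded region so that subregion measurements are free of rim truncation
bias, mimicking cortex that continues beyond the measured region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_stats import assign_education_group, assign_risk_level
from .volume_io import (
    LABEL_CSF,
    LABEL_GM,
    LABEL_WM,
    SUBREGION_CODES,
    SUBREGION_NAMES,
    TissueLabelVolume,
)

RISK_LEVELS = ("low", "intermediate", "high")


class SpecValidationError(ValueError):
    """Raised when a generator spec violates its invariants."""


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

SHAPE_KINDS = ("flat_slab", "cylindrical_shell", "folded_c_sheet")


@dataclass
class PhantomSpec:
    """Geometry of a synthetic gray-matter sheet phantom.

    ``sheet_thickness_mm`` may be a scalar or one value per subregion band.
    The sheet normal lies in-plane (axes 0/1) for the shell shapes and along
    axis 0 for the slab; thickness must be at least two voxels along the
    normal.  Default spacing emulates a 0.39 x 0.39 x 3 mm acquisition.
    """

    shape_kind: str = "folded_c_sheet"
    sheet_thickness_mm: float | Sequence[float] = 2.5
    voxel_spacing_mm: tuple[float, float, float] = (0.39, 0.39, 3.0)
    grid_dims: tuple[int, int, int] = (64, 64, 19)
    n_subregion_bands: int = 7
    label_noise_fraction: float = 0.0
    seed: int = 0

    def thickness_per_band(self) -> np.ndarray:
        t = np.atleast_1d(np.asarray(self.sheet_thickness_mm, float))
        if t.size == 1:
            t = np.full(self.n_subregion_bands, float(t[0]))
        if t.size != self.n_subregion_bands:
            raise SpecValidationError(
                "sheet_thickness_mm: expected a scalar or "
                f"{self.n_subregion_bands} per-band values, got {t.size}"
            )
        return t

    def validate(self) -> None:
        if self.shape_kind not in SHAPE_KINDS:
            raise SpecValidationError(f"shape_kind: must be one of {SHAPE_KINDS}")
        if not (1 <= self.n_subregion_bands <= 7):
            raise SpecValidationError("n_subregion_bands: must be in [1, 7]")
        if not (0 <= self.label_noise_fraction < 1):
            raise SpecValidationError("label_noise_fraction: must be in [0, 1)")
        sp = self.voxel_spacing_mm
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise SpecValidationError("voxel_spacing_mm: must be 3 positive reals")
        if len(self.grid_dims) != 3 or any(int(d) != d or d < 8 for d in self.grid_dims):
            raise SpecValidationError("grid_dims: must be 3 integers >= 8")
        t = self.thickness_per_band()
        if np.any(t <= 0):
            raise SpecValidationError("sheet_thickness_mm: must be positive")
        # thickness >= 2 voxels along the sheet-normal direction
        normal_spacing = (
            sp[0] if self.shape_kind == "flat_slab" else max(sp[0], sp[1])
        )
        if np.any(t < 2 * normal_spacing):
            raise SpecValidationError(
                "sheet_thickness_mm: sheet must span at least two voxels along "
                f"its normal (< {2 * normal_spacing:.3f} mm at this spacing)"
            )


def _apply_label_noise(labels: np.ndarray, fraction: float, rng) -> None:
    """Reassign a fraction of banded GM voxels to a random different band."""
    if fraction <= 0:
        return
    banded = np.flatnonzero(np.isin(labels.ravel(), SUBREGION_CODES))
    n_flip = int(round(fraction * banded.size))
    if n_flip == 0:
        return
    present = np.unique(labels.ravel()[banded])
    if present.size < 2:
        return
    flip = rng.choice(banded, size=n_flip, replace=False)
    flat = labels.ravel()
    for idx in flip:
        others = present[present != flat[idx]]
        flat[idx] = rng.choice(others)


def _slab_phantom(spec: PhantomSpec) -> tuple[TissueLabelVolume, np.ndarray]:
    sx, sy, sz = spec.voxel_spacing_mm
    nx, ny, nz = (int(d) for d in spec.grid_dims)
    t_band = spec.thickness_per_band()
    n_vox = np.maximum(np.round(t_band / sx).astype(int), 2)
    margin, wm_thick = 2, 2
    need_x = margin + wm_thick + int(n_vox.max()) + 2 + margin
    if nx < need_x:
        raise SpecValidationError(
            f"grid_dims: axis 0 needs >= {need_x} voxels for sheet + margins, got {nx}"
        )
    # plain-GM flanks keep labeled bands clear of rim truncation
    fy = int(math.ceil(t_band.max() / (2 * sy))) + 1
    fz = int(math.ceil(t_band.max() / (2 * sz))) + 1
    band_lo, band_hi = margin + fy, ny - margin - fy
    if band_hi - band_lo < spec.n_subregion_bands:
        raise SpecValidationError(
            "grid_dims: axis 1 too small for "
            f"{spec.n_subregion_bands} bands plus flanks"
        )

    labels = np.zeros((nx, ny, nz), dtype=np.int16)
    gt = np.zeros((nx, ny, nz), dtype=float)
    edges = np.linspace(band_lo, band_hi, spec.n_subregion_bands + 1).round().astype(int)

    y_band = np.full(ny, -1)  # band index per length position, -1 on flanks
    for b in range(spec.n_subregion_bands):
        y_band[edges[b]:edges[b + 1]] = b
    # clamp flank thickness to the adjacent band
    band_of_y = y_band.copy()
    band_of_y[margin:band_lo] = 0
    band_of_y[band_hi:ny - margin] = spec.n_subregion_bands - 1

    gm_base = margin + wm_thick
    for y in range(margin, ny - margin):
        b = band_of_y[y]
        n = int(n_vox[b])
        labels[margin:gm_base, y, margin:nz - margin] = LABEL_WM
        code = LABEL_GM if y_band[y] < 0 else SUBREGION_CODES[y_band[y]]
        zl, zh = margin + fz, nz - margin - fz
        labels[gm_base:gm_base + n, y, margin:nz - margin] = LABEL_GM
        if y_band[y] >= 0 and zh > zl:
            labels[gm_base:gm_base + n, y, zl:zh] = code
        labels[gm_base + n:nx - margin, y, margin:nz - margin] = LABEL_CSF
        gt[gm_base:gm_base + n, y, margin:nz - margin] = n * sx
    return TissueLabelVolume(labels, spec.voxel_spacing_mm), gt


def _shell_phantom(spec: PhantomSpec) -> tuple[TissueLabelVolume, np.ndarray]:
    sx, sy, sz = spec.voxel_spacing_mm
    nx, ny, nz = (int(d) for d in spec.grid_dims)
    t_band = spec.thickness_per_band()
    t_max = float(t_band.max())
    margin = 2
    s_plane = max(sx, sy)

    cx, cy = (nx - 1) / 2 * sx, (ny - 1) / 2 * sy
    half_extent = min((nx - 1) / 2 * sx, (ny - 1) / 2 * sy)
    r_out_max = half_extent - 2 * margin * s_plane
    r_in = r_out_max - t_max
    if r_in < 2 * s_plane:
        raise SpecValidationError(
            "grid_dims: in-plane grid too small for shell radius plus margins"
        )

    x = np.arange(nx) * sx - cx
    y = np.arange(ny) * sy - cy
    r = np.sqrt(x[:, None] ** 2 + y[None, :] ** 2)
    theta = np.arctan2(y[None, :], x[:, None] * np.ones((1, ny)))

    r_mid = r_in + t_max / 2
    phi_flank = (t_max / 2 + s_plane) / r_mid
    if spec.shape_kind == "cylindrical_shell":
        # nearly full annulus with a narrow cut so the sheet is developable
        # (a closed tube has no isometric planar unrolling); the cut must be
        # wider than the neighbourhood diagonal to avoid geodesic shortcuts
        phi_cut = 1.5 * s_plane / r_in
        th_lo, th_hi = -math.pi + phi_cut, math.pi - phi_cut
    else:  # folded C: 270 degree sector, opening toward -x
        th_lo, th_hi = -0.75 * math.pi, 0.75 * math.pi

    b_lo, b_hi = th_lo + phi_flank, th_hi - phi_flank
    if b_hi - b_lo <= 0:
        raise SpecValidationError("grid_dims: shell too small for angular flanks")
    band_edges = np.linspace(b_lo, b_hi, spec.n_subregion_bands + 1)

    in_sector = (theta >= th_lo) & (theta < th_hi)
    band_idx = np.clip(
        np.searchsorted(band_edges, theta, side="right") - 1,
        0, spec.n_subregion_bands - 1,
    )
    t_here = t_band[band_idx]
    gm_plane = in_sector & (r >= r_in) & (r < r_in + t_here)
    wm_plane = r < r_in
    labeled_plane = gm_plane & (theta >= b_lo) & (theta < b_hi)

    labels = np.zeros((nx, ny, nz), dtype=np.int16)
    gt = np.zeros((nx, ny, nz), dtype=float)
    fz = int(math.ceil(t_max / (2 * sz))) + 1
    zl, zh = margin + fz, nz - margin - fz

    plane_labels = np.full((nx, ny), LABEL_CSF, dtype=np.int16)
    plane_labels[wm_plane] = LABEL_WM
    plane_labels[gm_plane] = LABEL_GM
    plane_banded = plane_labels.copy()
    codes = np.asarray(SUBREGION_CODES[: spec.n_subregion_bands], dtype=np.int16)
    plane_banded[labeled_plane] = codes[band_idx[labeled_plane]]

    for z in range(margin, nz - margin):
        labels[:, :, z] = plane_banded if (zl <= z < zh and zh > zl) else plane_labels
        gt[:, :, z][gm_plane] = t_here[gm_plane]
    labels[:margin], labels[-margin:] = 0, 0
    labels[:, :margin], labels[:, -margin:] = 0, 0
    return TissueLabelVolume(labels, spec.voxel_spacing_mm), gt


def generate_phantom(spec: PhantomSpec) -> tuple[TissueLabelVolume, np.ndarray]:
    """Generate a phantom volume and its per-voxel ground-truth thickness map.

    Returns ``(volume, gt)`` where ``gt`` is a float array holding the true
    geometric sheet thickness (mm) on GM voxels and 0 elsewhere.  For the
    slab the truth is the realised discrete thickness (voxel count x
    spacing); for the curved shells it is the nominal band thickness.
    """
    spec.validate()
    if spec.shape_kind == "flat_slab":
        vol, gt = _slab_phantom(spec)
    else:
        vol, gt = _shell_phantom(spec)
    _apply_label_noise(vol.labels, spec.label_noise_fraction, np.random.default_rng(spec.seed))
    return vol, gt


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: correlation targets between education years and thickness, per risk stratum.
#: High-risk values are the reported stratified correlations (CA1 showed none);
#: intermediate has one firm value (PHC), one near-threshold (ERC) and weak
#: trends elsewhere; low risk shows no association by design.
DEFAULT_TARGET_R: dict[str, dict[str, float]] = {
    "low": {name: 0.0 for name in SUBREGION_NAMES},
    "intermediate": {
        "CA23DG": 0.25, "CA1": 0.10, "SUB": 0.25, "ERC": 0.44,
        "PRC": 0.25, "PHC": 0.45, "FUS": 0.25,
    },
    "high": {
        "CA23DG": 0.63, "CA1": 0.0, "SUB": 0.47, "ERC": 0.58,
        "PRC": 0.73, "PHC": 0.72, "FUS": 0.61,
    },
}

#: combined (across-subregion mean) correlation target in the high-risk stratum
DEFAULT_TARGET_R_COMBINED_HIGH = 0.77

#: plausible mean subregional thickness (mm) for a mildly impaired AD sample,
#: chosen so the cohort-wide mean sits near 2.2-2.3 mm
DEFAULT_BASE_THICKNESS = {
    "CA23DG": 2.05, "CA1": 2.10, "SUB": 2.25, "ERC": 2.40,
    "PRC": 2.45, "PHC": 2.25, "FUS": 2.50,
}

# education is drawn per group as discrete uniform integers: lower on
# {10..13} (mean 11.5), higher on {14..19} (mean 16.5).  Disjoint supports
# guarantee the below/above-mean allocation reproduces the group sizes for
# every seed; the group means approximate the reported 11.5 / 16.2.
_EDU_LOWER = (10, 13)
_EDU_HIGHER = (14, 19)


def _edu_moments(n_lower: int, n_higher: int) -> tuple[float, float]:
    """Population mean and SD of education under the group-mixture draw."""

    def uniform_stats(lo, hi):
        k = hi - lo + 1
        return (lo + hi) / 2, (k ** 2 - 1) / 12

    m_l, v_l = uniform_stats(*_EDU_LOWER)
    m_h, v_h = uniform_stats(*_EDU_HIGHER)
    p_l = n_lower / (n_lower + n_higher)
    p_h = 1 - p_l
    mean = p_l * m_l + p_h * m_h
    var = p_l * (v_l + (m_l - mean) ** 2) + p_h * (v_h + (m_h - mean) ** 2)
    return mean, math.sqrt(var)


#: education SD implied by the default 32/26 group mixture; the scale used to
#: convert target correlations into mm/year slopes
EDUCATION_SD_REF = _edu_moments(32, 26)[1]


def slope_from_target_r(r: float, residual_sd: float, edu_sd: float = EDUCATION_SD_REF) -> float:
    """Education slope (mm/year) giving Pearson r at the configured noise level.

    From ``r = s*sigma_e / sqrt(s^2 sigma_e^2 + sigma^2)`` solved for s.
    """
    if not -1 < r < 1:
        raise ValueError("target r must be in (-1, 1)")
    return r / math.sqrt(1 - r * r) * residual_sd / edu_sd


def shared_noise_fraction_from_targets(
    target_r_high: Mapping[str, float], target_r_combined: float
) -> float:
    """Across-subregion noise-variance fraction matching the combined-mean r.

    With per-region slopes fixed by their own targets, the correlation of the
    7-region mean depends on how much residual variance the regions share:
    ``r_comb = gbar / sqrt(gbar^2 + c + (1-c)/7)`` with ``g = r/sqrt(1-r^2)``.
    Solving for the shared fraction c gives ``c = (7*A - 1)/6`` where
    ``A = gbar^2 (1/r_comb^2 - 1)``.
    """
    g = np.array([r / math.sqrt(1 - r * r) for r in target_r_high.values()])
    gbar = float(g.mean())
    a = gbar ** 2 * (1 / target_r_combined ** 2 - 1)
    return float(np.clip((7 * a - 1) / 6, 0.0, 0.95))


def default_slopes(residual_sd: float = 0.15) -> dict[str, dict[str, float]]:
    return {
        level: {
            name: slope_from_target_r(r, residual_sd)
            for name, r in by_region.items()
        }
        for level, by_region in DEFAULT_TARGET_R.items()
    }


@dataclass
class CohortSpec:
    """Statistical structure of the synthetic patient cohort.

    Defaults reproduce the demographic table of the emulated 58-patient
    sample exactly: group sizes, female counts, APOE genotype counts,
    family-history counts and 4 subjects without the MRI sequence.  Per-risk
    stratum sizes are not fixed; they follow from genotype x family history
    with family history assigned independently within education groups.
    """

    n_lower: int = 32
    n_higher: int = 26
    education_range_years: tuple[int, int] = (9, 21)
    age_mean_sd_by_group: tuple[tuple[float, float], tuple[float, float]] = (
        (71.8, 7.0), (73.8, 6.3))
    mmse_mean_sd_by_group: tuple[tuple[float, float], tuple[float, float]] = (
        (21.1, 5.2), (24.7, 4.2))
    female_counts: tuple[int, int] = (18, 9)
    apoe_genotype_counts: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"2/3": (2, 1), "3/3": (12, 6), "3/4": (13, 14), "4/4": (5, 5)})
    fh_counts: tuple[int, int] = (9, 13)
    n_missing_mri: int = 4
    base_thickness_mm_by_subregion: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_THICKNESS))
    education_slope_by_risklevel_and_subregion: Mapping[str, Mapping[str, float]] | None = None
    residual_sd_mm: float = 0.15
    shared_noise_fraction: float | None = None
    seed: int = 0

    def slopes(self) -> Mapping[str, Mapping[str, float]]:
        if self.education_slope_by_risklevel_and_subregion is not None:
            return self.education_slope_by_risklevel_and_subregion
        return default_slopes(self.residual_sd_mm)

    def shared_fraction(self) -> float:
        if self.shared_noise_fraction is not None:
            return float(self.shared_noise_fraction)
        return shared_noise_fraction_from_targets(
            DEFAULT_TARGET_R["high"], DEFAULT_TARGET_R_COMBINED_HIGH)

    def validate(self) -> None:
        n = (self.n_lower, self.n_higher)
        if any(v < 0 for v in n) or sum(n) < 2:
            raise SpecValidationError("n_lower/n_higher: need at least 2 subjects")
        for g in (0, 1):
            geno_sum = sum(c[g] for c in self.apoe_genotype_counts.values())
            if geno_sum != n[g]:
                raise SpecValidationError(
                    f"apoe_genotype_counts: group {g} counts sum to {geno_sum}, "
                    f"expected {n[g]}")
            if not (0 <= self.female_counts[g] <= n[g]):
                raise SpecValidationError("female_counts: exceeds group size")
            if not (0 <= self.fh_counts[g] <= n[g]):
                raise SpecValidationError("fh_counts: exceeds group size")
        if not (0 <= self.n_missing_mri <= sum(n)):
            raise SpecValidationError("n_missing_mri: out of range")
        if self.residual_sd_mm <= 0:
            raise SpecValidationError("residual_sd_mm: must be positive")
        slopes = self.slopes()
        if any(abs(s) > 1e-12 for s in slopes.get("low", {}).values()):
            raise SpecValidationError("education slopes for the low-risk level must be zero")
        high = slopes.get("high", {})
        if high and any(high["CA1"] > high[r] + 1e-12 for r in high if r != "CA1"):
            raise SpecValidationError(
                "CA1 slope must not exceed other subregions' slopes at high risk")

    def scaled(self, factor: int) -> "CohortSpec":
        """Scale every count by an integer factor (for calibration runs)."""
        return CohortSpec(
            n_lower=self.n_lower * factor,
            n_higher=self.n_higher * factor,
            education_range_years=self.education_range_years,
            age_mean_sd_by_group=self.age_mean_sd_by_group,
            mmse_mean_sd_by_group=self.mmse_mean_sd_by_group,
            female_counts=tuple(c * factor for c in self.female_counts),
            apoe_genotype_counts={
                k: (a * factor, b * factor)
                for k, (a, b) in self.apoe_genotype_counts.items()},
            fh_counts=tuple(c * factor for c in self.fh_counts),
            n_missing_mri=self.n_missing_mri * factor,
            base_thickness_mm_by_subregion=self.base_thickness_mm_by_subregion,
            education_slope_by_risklevel_and_subregion=self.education_slope_by_risklevel_and_subregion,
            residual_sd_mm=self.residual_sd_mm,
            shared_noise_fraction=self.shared_noise_fraction,
            seed=self.seed,
        )


THICKNESS_COLUMNS = [f"thick_{name}" for name in SUBREGION_NAMES]


def generate_cohort_table(spec: CohortSpec) -> pd.DataFrame:
    """Generate one synthetic cohort as a tidy subject table.

    Categorical marginals (gender, genotype, family history, group sizes)
    equal the spec counts exactly for every seed; continuous variables are
    drawn from the configured distributions.  Columns: subject_id, age_years,
    gender, education_years, education_group, apoe_genotype, family_history,
    risk_level, mmse, mri_available, thick_<subregion> x7, thick_mean.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = (spec.n_lower, spec.n_higher)

    # draw educations jointly, conditioned on the cohort mean separating the
    # group supports so the below/above-mean rule reproduces the group sizes
    for _ in range(1000):
        edu_groups = [
            rng.integers(lo, hi + 1, size=n[g])
            for g, (lo, hi) in enumerate((_EDU_LOWER, _EDU_HIGHER))
        ]
        mean_edu = float(np.concatenate(edu_groups).mean()) if sum(n) else 0.0
        if (not n[0] or edu_groups[0].max() < mean_edu) and (
                not n[1] or edu_groups[1].min() >= mean_edu):
            break
    else:  # pragma: no cover - bounded-retry guard
        raise SpecValidationError(
            "education draw inconsistent with below/above-mean group allocation")

    rows = []
    for g, group in enumerate(("lower", "higher")):
        edu = edu_groups[g]
        age_m, age_s = spec.age_mean_sd_by_group[g]
        mmse_m, mmse_s = spec.mmse_mean_sd_by_group[g]
        age = rng.normal(age_m, age_s, size=n[g]).round(1)
        mmse = np.clip(np.round(rng.normal(mmse_m, mmse_s, size=n[g])), 0, 30).astype(int)
        female = np.zeros(n[g], bool)
        female[: spec.female_counts[g]] = True
        rng.shuffle(female)
        fh = np.zeros(n[g], bool)
        fh[: spec.fh_counts[g]] = True
        rng.shuffle(fh)  # independent of genotype: the independence reading
        geno = np.concatenate([
            np.full(cnt[g], name)
            for name, cnt in spec.apoe_genotype_counts.items()
        ])
        rng.shuffle(geno)
        for i in range(n[g]):
            rows.append({
                "age_years": float(age[i]),
                "gender": "female" if female[i] else "male",
                "education_years": int(edu[i]),
                "education_group": group,
                "apoe_genotype": str(geno[i]),
                "family_history": bool(fh[i]),
                "mmse": int(mmse[i]),
            })
    df = pd.DataFrame(rows)
    df.insert(0, "subject_id", [f"S{i:04d}" for i in range(len(df))])
    df["risk_level"] = [
        assign_risk_level(g, f)
        for g, f in zip(df["apoe_genotype"], df["family_history"])
    ]
    # the conditioned draw guarantees consistency with the threshold rule
    derived = [assign_education_group(y, mean_edu) for y in df["education_years"]]
    assert list(df["education_group"]) == derived

    missing = rng.choice(len(df), size=spec.n_missing_mri, replace=False)
    df["mri_available"] = True
    df.loc[missing, "mri_available"] = False

    slopes = spec.slopes()
    c = spec.shared_fraction()
    sigma = spec.residual_sd_mm
    z_shared = rng.normal(size=len(df))
    centered = df["education_years"].to_numpy(float) - mean_edu
    for name in SUBREGION_NAMES:
        base = float(spec.base_thickness_mm_by_subregion[name])
        s = np.array([slopes[rl][name] for rl in df["risk_level"]])
        noise = math.sqrt(c) * sigma * z_shared + math.sqrt(1 - c) * sigma * rng.normal(size=len(df))
        df[f"thick_{name}"] = base + s * centered + noise
    df["thick_mean"] = df[THICKNESS_COLUMNS].mean(axis=1)
    return df


def generate_subject_volumes(
    cohort: pd.DataFrame, spec: PhantomSpec
) -> dict[str, tuple[TissueLabelVolume, np.ndarray]]:
    """One phantom per MRI-available subject, band thickness = subject thickness.

    The phantom spec acts as a geometric template; its per-band thickness is
    replaced by the subject's seven simulated subregional values.  Seeds are
    derived from the template seed plus the subject index so volumes are
    byte-identical across reruns.
    """
    if spec.n_subregion_bands != len(SUBREGION_NAMES):
        raise SpecValidationError("subject phantoms need all 7 subregion bands")
    out: dict[str, tuple[TissueLabelVolume, np.ndarray]] = {}
    for i, row in cohort[cohort["mri_available"]].iterrows():
        thick = [float(row[f"thick_{name}"]) for name in SUBREGION_NAMES]
        sub_spec = PhantomSpec(
            shape_kind=spec.shape_kind,
            sheet_thickness_mm=thick,
            voxel_spacing_mm=spec.voxel_spacing_mm,
            grid_dims=spec.grid_dims,
            n_subregion_bands=len(SUBREGION_NAMES),
            label_noise_fraction=spec.label_noise_fraction,
            seed=int(spec.seed) + int(i),
        )
        out[str(row["subject_id"])] = generate_phantom(sub_spec)
    return out


def cohort_to_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def cohort_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "education_years", "education_group", "risk_level",
                "mri_available", "thick_mean"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    return df
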