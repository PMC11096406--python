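"""Seeded synthetic cohorts of uniaxial tensile records.

No tensile data for full-thickness burn human skin are publicly deposited,
so every downstream stage of the pipeline is exercised on synthetic cohorts
whose distributional structure matches what the analysis assumes: three
loading-rate classes (0.3, 2.0, 8.0 mm/s; 95/92/102 specimens), per-specimen
material parameters that are strictly positive and strongly right-skewed,
and stress-strain curves that follow the Veronda-Westmann law up to
multiplicative measurement noise.

Per-specimen (mu, gamma, rupture strain) are drawn from lognormal laws
calibrated by median and quartiles.  For a lognormal, ln X is normal with

    location = ln(median)        scale = ln(q75/q25) / (2 * z_0.75)

where z_0.75 ~ 0.67449 is the standard normal upper quartile, i.e. the
log-symmetric law whose quartile ratio reproduces the requested one.  The
default triplets are the pooled cohort quartiles reported for burn skin
(mu: 0.32/0.17/0.66 MPa; gamma: 0.07/0.01/0.12; rupture strain:
1.69/1.27/2.47).  gamma's quartiles are not log-symmetric about its median,
so its calibrated law matches the median and the quartile *ratio* only
approximately at each fence — a documented approximation.

UT stress and toughness are deliberately NOT sampled: they emerge from
(mu, gamma, rupture strain) through the constitutive law, mirroring the
physical coupling between stiffness, stiffening and failure strain.

The loading-rate label is by default a pure label (``rate_effect = 0``):
the generating law is rate-independent, encoding the null hypothesis the
statistical pipeline is designed to probe.  Setting ``rate_effect > 0``
shifts the log-location of every material parameter of class k by
``k * rate_effect * scale`` (classes ordered by rate), giving a graded,
standardized between-rate effect for power studies.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .constitutive import kinematics

__all__ = [
    "ParameterDistribution",
    "SyntheticCohortConfig",
    "TensileRecord",
    "TABLE_MU",
    "TABLE_GAMMA",
    "TABLE_UT_STRAIN",
    "TABLE_UT_STRESS",
    "TABLE_TOUGHNESS",
    "calibrate_lognormal",
    "generate_cohort",
    "write_cohort",
    "read_record",
    "read_cohort",
    "derive_seed",
]

_Z75 = norm.ppf(0.75)  # 0.6744897501960817

# additive stress floor (MPa) applied with nonzero noise so a noisy draw can
# never produce a non-positive stress sample
STRESS_FLOOR = 1e-4


@dataclass(frozen=True)
class ParameterDistribution:
    """Median / 25th / 75th percentile triplet of a positive material parameter."""

    median: float
    q25: float
    q75: float

    def __post_init__(self) -> None:
        if not (0 < self.q25 < self.median < self.q75):
            raise ValueError(
                f"require 0 < q25 < median < q75, got ({self.q25}, {self.median}, {self.q75})"
            )


# pooled-cohort calibration triplets for burn skin (units: MPa for stresses
# and mu; dimensionless for strain and gamma)
TABLE_UT_STRESS = ParameterDistribution(1.73, 0.97, 3.20)
TABLE_UT_STRAIN = ParameterDistribution(1.69, 1.27, 2.47)
TABLE_TOUGHNESS = ParameterDistribution(1.38, 0.64, 2.65)
TABLE_MU = ParameterDistribution(0.32, 0.17, 0.66)
TABLE_GAMMA = ParameterDistribution(0.07, 0.01, 0.12)

# ASTM D638 Type V gauge section: length 7.62 mm, width 3.18 mm; specimen
# thickness set to the cohort mean of 2.1 mm
DEFAULT_GAUGE_LENGTH_MM = 7.62
DEFAULT_AREA_MM2 = 3.18 * 2.1


@dataclass(frozen=True)
class TensileRecord:
    """Raw uniaxial tensile record for one specimen.

    ``displacement`` (mm, nondecreasing from 0) and ``force`` (N) are
    equal-length series; ``gauge_length`` L0 (mm) and ``area`` A0 (mm^2)
    describe the undeformed gauge section.
    """

    sample_id: str
    rate_class: float
    displacement: np.ndarray
    force: np.ndarray
    gauge_length: float
    area: float
    thickness: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "displacement", np.asarray(self.displacement, dtype=float))
        object.__setattr__(self, "force", np.asarray(self.force, dtype=float))
        if self.displacement.shape != self.force.shape or self.displacement.size < 2:
            raise ValueError("displacement and force must be equal-length series of >= 2 points")
        if self.displacement[0] != 0:
            raise ValueError("displacement must start at 0")
        if not (self.gauge_length > 0 and self.area > 0):
            raise ValueError("gauge length and area must be positive")


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Configuration of a three-class synthetic tensile cohort.

    Defaults reproduce the screened cohort sizes (95, 92, 102) at rates
    (0.3, 2.0, 8.0 mm/s) with a rate-independent generating law
    (``rate_effect = 0``) and 3% multiplicative stress noise.
    """

    n_per_class: tuple[int, int, int] = (95, 92, 102)
    rate_classes: tuple[float, float, float] = (0.3, 2.0, 8.0)
    mu_dist: ParameterDistribution = TABLE_MU
    gamma_dist: ParameterDistribution = TABLE_GAMMA
    rupture_strain_dist: ParameterDistribution = TABLE_UT_STRAIN
    rate_effect: float = 0.0
    noise_cv: float = 0.03
    n_points: int = 100
    gauge_length_mm: float = DEFAULT_GAUGE_LENGTH_MM
    area_mm2: float = DEFAULT_AREA_MM2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_class) != 3 or any(n < 1 for n in self.n_per_class):
            raise ValueError("n_per_class must be three positive integers")
        if len(self.rate_classes) != 3:
            raise ValueError("rate_classes must list three loading rates")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        if self.n_points < 20:
            raise ValueError("n_points must be >= 20")
        if not (self.gauge_length_mm > 0 and self.area_mm2 > 0):
            raise ValueError("gauge geometry must be positive")


def calibrate_lognormal(dist: ParameterDistribution) -> tuple[float, float]:
    """Lognormal (location, scale) on the log scale matching a quartile triplet.

    location = ln(median); scale = ln(q75/q25)/(2*z_0.75).  For a triplet
    that is exactly log-symmetric the calibrated law reproduces q25 and q75
    exactly; otherwise it matches the median and the geometric mean of the
    two quartile ratios.
    """
    return float(np.log(dist.median)), float(np.log(dist.q75 / dist.q25) / (2.0 * _Z75))


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2^31) from one master seed."""
    return int(np.random.SeedSequence([seed, zlib.crc32(stage.encode())]).generate_state(1)[0] % (2**31))


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[list[TensileRecord], pd.DataFrame]:
    """Draw a seeded synthetic cohort of tensile records.

    For each class k (ordered by rate) and specimen, (mu, gamma, rupture
    strain) are drawn from the calibrated lognormal laws with the class's
    log-location shifted by ``k * rate_effect * scale``; nominal stress is
    evaluated on an even strain grid [0, rupture strain], perturbed by
    multiplicative Gaussian noise of coefficient of variation ``noise_cv``
    (floored at 1e-4 MPa when noise is on), and converted back to force and
    displacement through the gauge geometry.

    Returns
    -------
    (records, truth)
        The tensile records and a truth table (sample_id, rate_mm_per_s,
        mu, gamma, rupture_strain) for parameter-recovery tests.  Identical
        config implies identical output.
    """
    rng = np.random.default_rng(config.seed)
    calib = {
        "mu": calibrate_lognormal(config.mu_dist),
        "gamma": calibrate_lognormal(config.gamma_dist),
        "rupture_strain": calibrate_lognormal(config.rupture_strain_dist),
    }
    records: list[TensileRecord] = []
    rows = []
    for k, (n, rate) in enumerate(zip(config.n_per_class, config.rate_classes)):
        for j in range(n):
            z = rng.standard_normal(3)
            mu, gamma, eps_r = (
                float(np.exp(loc + k * config.rate_effect * scale + scale * zi))
                for (loc, scale), zi in zip(calib.values(), z)
            )
            strain = np.linspace(0.0, eps_r, config.n_points)
            # far-tail gamma draws would otherwise overflow float64; the cap
            # only touches specimens the 3*IQR screen removes anyway
            kin = kinematics(strain)
            expo = np.minimum(gamma * (kin.i1_bar - 3.0), 80.0)
            sigma = 2.0 * mu * (1.0 - kin.stretch**-3) * (
                kin.stretch * np.exp(expo) - 1.0
            )
            if config.noise_cv > 0:
                noise = 1.0 + config.noise_cv * rng.standard_normal(config.n_points)
                sigma = np.maximum(sigma * noise, STRESS_FLOOR)
            sample_id = f"r{rate:g}-{j:04d}"
            records.append(
                TensileRecord(
                    sample_id=sample_id,
                    rate_class=rate,
                    displacement=strain * config.gauge_length_mm,
                    force=sigma * config.area_mm2,
                    gauge_length=config.gauge_length_mm,
                    area=config.area_mm2,
                )
            )
            rows.append(
                {"sample_id": sample_id, "rate_mm_per_s": rate,
                 "mu": mu, "gamma": gamma, "rupture_strain": eps_r}
            )
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plain-text cohort I/O


def write_cohort(
    records: Sequence[TensileRecord],
    outdir: str | Path,
    truth: pd.DataFrame | None = None,
    seed: int | None = None,
) -> Path:
    """Write one delimited text file per specimen plus a manifest (and truth) CSV.

    Each specimen file carries a ``#``-prefixed header with the sample id,
    rate and gauge geometry, followed by ``displacement_mm,force_N`` rows.
    Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for rec in records:
        fname = f"{rec.sample_id}.csv"
        with open(outdir / fname, "w") as fh:
            fh.write(f"# sample_id: {rec.sample_id}\n")
            fh.write(f"# rate_mm_per_s: {rec.rate_class:g}\n")
            fh.write(f"# gauge_length_mm: {rec.gauge_length!r}\n")
            fh.write(f"# area_mm2: {rec.area!r}\n")
            fh.write("displacement_mm,force_N\n")
            for d, f in zip(rec.displacement, rec.force):
                # shortest round-trip decimal representation
                fh.write(f"{float(d)!r},{float(f)!r}\n")
        manifest.append(
            {"sample_id": rec.sample_id, "file": fname, "rate_mm_per_s": rec.rate_class,
             "gauge_length_mm": rec.gauge_length, "area_mm2": rec.area}
        )
    mdf = pd.DataFrame(manifest)
    if seed is not None:
        mdf["seed"] = seed
    manifest_path = outdir / "manifest.csv"
    mdf.to_csv(manifest_path, index=False)
    if truth is not None:
        truth.to_csv(outdir / "truth.csv", index=False)
    return manifest_path


def read_record(
    path: str | Path,
    gauge_length: float | None = None,
    area: float | None = None,
    rate_class: float = float("nan"),
) -> TensileRecord:
    """Read one specimen file written by :func:`write_cohort`.

    Also accepts a headerless two-column CSV, in which case the gauge
    geometry (and optionally the rate) must be supplied explicitly.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            key, _, val = line.lstrip("#").partition(":")
            meta[key.strip()] = val.strip()
            body_start += 1
        else:
            break
    if body_start < len(lines) and lines[body_start].lstrip()[:1].isalpha():
        body_start += 1  # column header row
    data = np.loadtxt(lines[body_start:], delimiter=",", ndmin=2)
    gl = gauge_length if gauge_length is not None else float(meta["gauge_length_mm"])
    a = area if area is not None else float(meta["area_mm2"])
    rate = float(meta.get("rate_mm_per_s", rate_class))
    return TensileRecord(
        sample_id=meta.get("sample_id", path.stem),
        rate_class=rate,
        displacement=data[:, 0],
        force=data[:, 1],
        gauge_length=gl,
        area=a,
    )


def read_cohort(indir: str | Path) -> list[TensileRecord]:
    """Read every specimen listed in a cohort directory's manifest."""
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    return [read_record(indir / row.file) for row in manifest.itertuples()]
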