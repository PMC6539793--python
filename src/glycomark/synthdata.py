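"""Synthetic cohorts, synthetic chromatograms, and packaged table fixtures.

The study design this package targets — a 20-case / 18-control plasma
cohort quantified over 42 strongly multicollinear, non-negative
glycated-peptide abundances — has no public raw data, so this module
generates statistically faithful stand-ins:

* cohort feature tables: per-feature log-normal abundances with
  block-equicorrelated structure (glycation sites on the same protein are
  correlated), positive log-scale shifts on a configurable differential
  feature set in cases only, and per-sample plasma protein concentrations;
* centroided LC-MS scan series with Gaussian elution peaks of known area
  and a flat noise baseline, for validating XIC extraction and integration;
* typed loaders for the packaged reference tables (annotated glycopeptide
  panel, protein half-lives, classifier validation summary, and the two
  cohort demographics tables).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .chrom import ScanSeries
from .quantify import CASE_LABEL, CONTROL_LABEL, FeatureTable

__all__ = [
    "CohortConfig",
    "ChromatogramConfig",
    "generate_cohort",
    "generate_chromatograms",
    "load_fixture",
    "FIXTURE_NAMES",
]

# Within-block correlation of log-abundances; glycation sites on one protein
# track the protein's exposure to glucose and are strongly collinear.
DEFAULT_BLOCK_R = 0.8
# Block sizes mirror the protein groupings of the annotated 42-peptide panel:
# 27 albumin sites, 6 serotransferrin, and the remaining proteins pooled.
DEFAULT_BLOCKS = (27, 6, 5, 4)


@dataclass
class CohortConfig:
    """Parameters of a synthetic case/control glycation cohort.

    Defaults reproduce the reference study design: 20 T2DM cases vs 18
    normoglycemic controls over 42 features; all features are differential
    with a +1.0 log-scale (about e-fold) upward shift in cases; plasma
    protein concentrations are drawn per group around 58.8 ± 9.85 (cases)
    and 61.9 ± 13.5 mg/mL (controls).
    """

    n_cases: int = 20
    n_controls: int = 18
    n_features: int = 42
    block_sizes: tuple[int, ...] = DEFAULT_BLOCKS
    block_r: float = DEFAULT_BLOCK_R
    log_mean_range: tuple[float, float] = (np.log(1e4), np.log(1e6))
    log_sigma: float = 0.5
    differential: tuple[int, ...] | None = None  # feature indices; None = all
    effect: float = 1.0  # log-scale shift added to cases
    conc_case: tuple[float, float] = (58.8, 9.85)  # mg/mL mean, SD
    conc_control: tuple[float, float] = (61.9, 13.5)
    seed: int | None = None

    def validate(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("both groups need at least one sample")
        if sum(self.block_sizes) != self.n_features:
            raise ValueError(
                f"block sizes {self.block_sizes} must sum to {self.n_features}"
            )
        if not -1.0 / (max(self.block_sizes) - 1) < self.block_r < 1.0:
            raise ValueError(
                "within-block correlation makes the correlation matrix "
                "non positive definite"
            )
        if self.differential is not None:
            bad = [i for i in self.differential if not 0 <= i < self.n_features]
            if bad:
                raise ValueError(f"differential feature indices out of range: {bad}")


@dataclass
class GroundTruth:
    """Generator-side record of what the synthetic cohort contains."""

    differential: tuple[int, ...]
    effect: float
    log_means: np.ndarray
    log_sigma: float
    block_of_feature: np.ndarray


def _block_correlation(block_sizes: tuple[int, ...], r: float) -> np.ndarray:
    d = sum(block_sizes)
    corr = np.eye(d)
    start = 0
    for size in block_sizes:
        corr[start : start + size, start : start + size] = r
        np.fill_diagonal(
            corr[start : start + size, start : start + size], 1.0
        )
        start += size
    return corr


def generate_cohort(cfg: CohortConfig) -> tuple[FeatureTable, GroundTruth]:
    """Draw a synthetic cohort feature table and its ground truth.

    Log-abundances are multivariate normal with block-equicorrelated
    structure; case samples get ``cfg.effect`` added on the log scale for
    every differential feature.  All abundances are strictly positive by
    construction (exponentiated), and the draw is deterministic under
    ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    d = cfg.n_features
    n = cfg.n_cases + cfg.n_controls

    corr = _block_correlation(cfg.block_sizes, cfg.block_r)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, d)) @ chol.T

    lo, hi = cfg.log_mean_range
    log_means = rng.uniform(lo, hi, size=d)
    diff = (
        tuple(range(d)) if cfg.differential is None else tuple(sorted(cfg.differential))
    )
    is_case = np.zeros(n, dtype=bool)
    is_case[: cfg.n_cases] = True

    log_abund = log_means + cfg.log_sigma * z
    for j in diff:
        log_abund[is_case, j] += cfg.effect
    abund = np.exp(log_abund)

    conc = np.empty(n)
    conc[is_case] = rng.normal(*cfg.conc_case, size=cfg.n_cases)
    conc[~is_case] = rng.normal(*cfg.conc_control, size=cfg.n_controls)
    conc = np.clip(conc, 10.0, None)  # Bradford readings are bounded away from 0

    block_of = np.concatenate(
        [np.full(size, b) for b, size in enumerate(cfg.block_sizes)]
    )
    sample_ids = [f"T2DM_{i + 1:02d}" for i in range(cfg.n_cases)] + [
        f"CTRL_{i + 1:02d}" for i in range(cfg.n_controls)
    ]
    features = [f"F{j + 1:02d}" for j in range(d)]
    table = FeatureTable(
        pd.DataFrame(abund, index=sample_ids, columns=features),
        pd.Series(
            [CASE_LABEL] * cfg.n_cases + [CONTROL_LABEL] * cfg.n_controls,
            index=sample_ids,
        ),
        pd.Series(conc, index=sample_ids),
    )
    truth = GroundTruth(diff, cfg.effect, log_means, cfg.log_sigma, block_of)
    return table, truth


@dataclass
class ChromatogramConfig:
    """Parameters of a synthetic centroided LC-MS run.

    Each target elutes as a Gaussian peak of known area at its retention
    time; centroids appear at the target m/z.  A flat baseline of random
    low-intensity centroids spans the acquisition m/z range, and the whole
    peak amplitude is jittered with a log-normal factor of coefficient of
    variation ``area_cv`` (run-to-run intensity variation).
    """

    targets: tuple[tuple[float, float, float], ...]  # (m/z, t_R min, area)
    sigma_t: float = 0.1  # chromatographic peak width, min
    time_span: tuple[float, float] = (0.0, 60.0)
    scan_interval: float = 1.0 / 30.0  # 2 s TOF scans, min
    mz_range: tuple[float, float] = (400.0, 2000.0)
    baseline_level: float = 0.0  # mean intensity of baseline centroids
    baseline_density: int = 20  # baseline centroids per scan
    area_cv: float = 0.0
    seed: int | None = None

    def validate(self) -> None:
        if self.sigma_t <= 0:
            raise ValueError("peak width must be positive")
        t0, t1 = self.time_span
        for mz, tr, area in self.targets:
            if not t0 <= tr <= t1:
                raise ValueError(f"retention time {tr} outside run span {self.time_span}")
            if area < 0:
                raise ValueError("true peak areas must be non-negative")
        mzs = sorted((tr, mz) for mz, tr, _ in self.targets)
        for (tr_a, mz_a), (tr_b, mz_b) in zip(mzs, mzs[1:]):
            if mz_a == mz_b and abs(tr_b - tr_a) < 2 * self.sigma_t:
                import warnings

                warnings.warn(
                    f"targets at m/z {mz_a} elute within 2 sigma of each other",
                    stacklevel=2,
                )


def generate_chromatograms(
    cfg: ChromatogramConfig,
) -> tuple[ScanSeries, dict[tuple[float, float], float]]:
    """Synthesize one centroided run; returns the series and realized areas.

    The realized area of each target (after the log-normal run-to-run
    jitter) is returned keyed by ``(m/z, t_R)`` so integration accuracy can
    be checked against ground truth.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    t0, t1 = cfg.time_span
    times = np.arange(t0, t1 + cfg.scan_interval / 2, cfg.scan_interval)

    factors = {}
    for mz, tr, area in cfg.targets:
        if cfg.area_cv > 0:
            sigma_ln = np.sqrt(np.log(1 + cfg.area_cv**2))
            f = float(rng.lognormal(-(sigma_ln**2) / 2, sigma_ln))
        else:
            f = 1.0
        factors[(mz, tr)] = f * area

    scans: list[np.ndarray] = []
    for t in times:
        rows = []
        for (mz, tr), realized in factors.items():
            amp = realized / (cfg.sigma_t * np.sqrt(2 * np.pi))
            inten = amp * np.exp(-((t - tr) ** 2) / (2 * cfg.sigma_t**2))
            if inten > 0:
                rows.append((mz, inten))
        if cfg.baseline_level > 0 and cfg.baseline_density > 0:
            noise_mz = rng.uniform(*cfg.mz_range, size=cfg.baseline_density)
            noise_int = rng.exponential(cfg.baseline_level, size=cfg.baseline_density)
            rows.extend(zip(noise_mz, noise_int))
        scans.append(np.array(rows, dtype=float).reshape(-1, 2))
    return ScanSeries(times, scans), factors


# ---------------------------------------------------------------------------
# Packaged reference-table fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("table1", "table2", "table3", "table4", "table5")

_FIXTURE_SHA256 = {
    "table1": "4d44aef5bb71313d8d3e7e1ce4bc4100a5bbe64afd4870bb71984e12b9ebc384",
    "table2": "33075a82773a855a2113e076a930e86f0c335ce15217958db1a4b8decbb55d4a",
    "table3": "aa902653fd1867de60dd797984fdc7254914683c240ef6ffaf485aed6e309950",
    "table4": "c36b7ebc7d608dde3577a768f09de871b64c5fc765238ad2e1ba061b493195a5",
    "table5": "601e38939bf3273f78990ee00b679fc95b3b3e90b49513e0be0dc8ccafc35271",
}


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the packaged reference tables as a typed DataFrame.

    ``table1``: the 42-row annotated glycopeptide panel (sequence in star
    notation, glycation site, retention time, observed m/z and charge
    states, U statistic, p-value, in-sample Ac/Sp/Sn, LDA variable label).
    ``table2``: plasma-protein half-lives.  ``table3``: LDA validation
    summary (LOOCV and sub-sample-trained Ac/Sp/Sn per variable set).
    ``table4``/``table5``: case and control cohort demographics.
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    ref = resources.files("glycomark.data").joinpath(f"{name}.tsv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise ValueError(
            f"fixture {name!r} failed its integrity check "
            f"(sha256 {digest} != {_FIXTURE_SHA256[name]})"
        )
    import io

    return pd.read_csv(io.BytesIO(raw), sep="\t")
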