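"""End-to-end orchestration: screen → feature selection → LDA validation.

A single configuration drives the whole downstream analysis of a cohort
feature table (synthetic or loaded from CSV): protein-content normalization,
Mann-Whitney screening with Holm control, randomized VIF filtering and/or
PCA reduction, and LDA validation in LOOCV and sub-sample-trained modes.
Reruns under the same configuration are deterministic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

from . import __version__
from .classify import loocv, subsample_validate
from .featsel import pca_select, randomized_vif_filter
from .quantify import FeatureTable, normalize_by_protein
from .stats import screen_features
from .synthdata import CohortConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    table_csv: str | None = None  # cohort CSV; None = generate synthetic
    alpha: float = 0.01
    vif_cutoffs: tuple[float, ...] = (5.0, 10.0)
    vif_runs: int = 1000
    pca_var_threshold: float = 0.95
    representation_fraction: float = 0.70
    n_train_per_class: int = 200
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if any(c <= 1 for c in self.vif_cutoffs):
            raise ValueError("VIF cutoffs must exceed 1")
        if self.vif_runs < 1 or self.n_train_per_class < 1:
            raise ValueError("run counts must be positive")

    def content_hash(self) -> str:
        payload = asdict(self)
        payload["version"] = __version__
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis and return a JSON-serializable report bundle.

    The bundle records provenance (config hash, seed, package version), the
    univariate screen, the VIF subset tallies, the PCA cut, and LOOCV plus
    sub-sample validation reports for every selected feature set.
    """
    cfg.validate()
    if cfg.table_csv is not None:
        table = FeatureTable.from_csv(cfg.table_csv)
    else:
        cohort_cfg = cfg.cohort
        if cohort_cfg.seed is None:
            cohort_cfg.seed = cfg.seed
        table, _ = generate_cohort(cohort_cfg)
    if table.abundances.empty:
        raise ValueError("feature table is empty")

    if table.protein_conc is not None:
        table = FeatureTable(
            normalize_by_protein(table.abundances, table.protein_conc),
            table.groups,
            table.protein_conc,
        )

    screen = screen_features(table, alpha=cfg.alpha)
    selected = list(screen.index[screen["significant"]])
    if not selected:  # fall back to the full panel if nothing passes
        selected = list(screen.index)
    X = table.abundances[selected]

    report: dict = {
        "provenance": {
            "config_hash": cfg.content_hash(),
            "seed": cfg.seed,
            "version": __version__,
        },
        "screen": screen.reset_index().to_dict(orient="records"),
        "n_significant": int(screen["significant"].sum()),
        "vif": {},
        "validation": [],
    }

    for k, cutoff in enumerate(cfg.vif_cutoffs):
        tally = randomized_vif_filter(
            X, cutoff=cutoff, runs=cfg.vif_runs, seed=cfg.seed + k
        )
        top_subset, top_count = tally.most_common(1)[0]
        report["vif"][f"cutoff_{cutoff:g}"] = {
            "tally": tally.to_json_dict(),
            "top_subset": list(top_subset),
            "top_count": top_count,
            "above_fraction": [
                list(s) for s in tally.above_fraction(cfg.representation_fraction)
            ],
        }
        loo = loocv(table, top_subset)
        sub = subsample_validate(
            table, top_subset, n_per_class=cfg.n_train_per_class, seed=cfg.seed + k
        )
        report["validation"].append(
            {"model": f"VIF{cutoff:g}", "loocv": loo.to_dict(), "subsample": sub.to_dict()}
        )

    basis, scores = pca_select(X, var_threshold=cfg.pca_var_threshold)
    report["pca"] = {
        "k": basis.k,
        "explained_variance_ratio": [float(v) for v in basis.explained_variance_ratio],
    }
    loo_pca = loocv(scores, y=table.case_mask)
    report["validation"].append({"model": "PCA", "loocv": loo_pca.to_dict()})
    return report
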