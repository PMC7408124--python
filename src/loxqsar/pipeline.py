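"""End-to-end orchestration: build -> descriptors -> filter -> split ->
GA selection -> validation -> prediction, plus the assay arithmetic.

The default pipeline honours the published train/test split and outlier
exclusion carried in the compound fixture; cluster-based re-selection of the
test set is available as an opt-in alternative. Every stochastic stage is
keyed to the single top-level seed, and the configuration is serialized into
the output bundle.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compounds import build_compound_table, compound_table_frame
from .descriptors import descriptor_matrix
from .filtering import (
    CorrelationPruner,
    FilterReport,
    MissingValueFilter,
    ZeroFractionFilter,
    select_test_set,
)
from .models import DescriptorMLR, GAConfig, GAFeatureSelector, predict_published
from .validation import build_validation_report

__all__ = [
    "PipelineConfig",
    "inhibition_rate",
    "log_activity",
    "run_pipeline",
]


def inhibition_rate(a_s: float, a_b: float, a_c: float) -> float:
    """Enzyme-inhibition percentage from assay absorbances.

    ``[1 - (A_S - A_B) / (A_C - A_B)] * 100`` with A_S the sample, A_B the
    blank and A_C the uninhibited control. May be negative (activation) or
    exceed 100.
    """
    if a_c == a_b:
        raise ZeroDivisionError("control and blank absorbances are equal")
    return (1.0 - (a_s - a_b) / (a_c - a_b)) * 100.0


def log_activity(pct: float) -> float:
    """Base-10 log of a positive inhibition percentage."""
    if not pct > 0:
        raise ValueError(f"activity must be positive to take log10, got {pct}")
    return math.log10(pct)


@dataclass
class PipelineConfig:
    seed: int = 17
    beta: float = 100.0
    carbon_scaled: bool = True
    zero_test_fraction: float = 0.1
    r2_threshold: float = 0.7
    split_source: str = "fixture"  # "fixture" | "clustering"
    n_test: int = 8
    exclude_outlier: bool = True
    ga: GAConfig = field(default_factory=GAConfig)
    n_scramble: int = 500
    output_dir: str = "loxqsar_run"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["version"] = __version__
        return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order and write the report bundle.

    Emits, under ``config.output_dir``: the compound table, descriptor
    matrix CSV with JSON sidecar, filter report, split assignment, ranked
    GA models, validation report (JSON and flat CSV), Williams-plot data,
    and a predictions CSV comparing the frozen published equation and the
    refit model against the tabulated values. Returns the in-memory objects.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"loxqsar {__version__} seed={config.seed}"]
    t0 = time.time()

    def stage(name):
        log.append(f"[{time.time() - t0:8.1f}s] {name}")

    stage("build compound table")
    records = build_compound_table()
    table = compound_table_frame()
    table.to_csv(out / "compounds.csv", index=False)
    modeled = [r for r in records if r.split != "excluded"]

    stage("compute descriptors")
    desc = descriptor_matrix(
        modeled,
        seed=config.seed,
        beta=config.beta,
        carbon_scaled=config.carbon_scaled,
    )
    desc.to_csv(out / "descriptors.csv")
    (out / "descriptors.json").write_text(
        json.dumps({**desc.attrs.get("weighting", {}), "version": __version__})
    )

    stage("filter descriptors")
    report = FilterReport()
    mv = MissingValueFilter().fit(desc)
    desc_f = mv.transform(desc)
    report = report.merge(mv.report_)
    zf = ZeroFractionFilter(config.zero_test_fraction).fit(desc_f)
    desc_f = zf.transform(desc_f)
    report = report.merge(zf.report_)
    cp = CorrelationPruner(config.r2_threshold).fit(desc_f)
    desc_f = cp.transform(desc_f)
    report = report.merge(cp.report_)
    (out / "filter_report.json").write_text(json.dumps(report.to_dict(), indent=1))

    y = np.array([r.log_lox for r in modeled])
    nos = np.array([r.no for r in modeled])

    stage(f"split ({config.split_source})")
    if config.split_source == "fixture":
        test_mask = np.array([r.split == "test" for r in modeled])
    elif config.split_source == "clustering":
        idx = select_test_set(desc_f.to_numpy(), y, config.n_test)
        test_mask = np.zeros(len(modeled), dtype=bool)
        test_mask[idx] = True
    else:
        raise ValueError(f"unknown split_source: {config.split_source!r}")
    pd.DataFrame({"no": nos, "split": np.where(test_mask, "test", "train")}).to_csv(
        out / "split.csv", index=False
    )
    train_mask = ~test_mask
    if config.exclude_outlier:
        train_mask &= np.array([not r.excluded_model2 for r in modeled])

    stage("GA model selection")
    ga = config.ga
    selector = GAFeatureSelector(
        subset_size=ga.subset_size,
        population_size=ga.population_size,
        generations=ga.generations,
        crossover_rate=ga.crossover_rate,
        mutation_rate=ga.mutation_rate,
        elitism=ga.elitism,
        patience=ga.patience,
        top_k=ga.top_k,
        random_state=config.seed,
    ).fit(desc_f.loc[nos[train_mask]], y[train_mask])
    (out / "models.json").write_text(
        json.dumps(
            {
                "ranking": [
                    {"descriptors": names, "q2_loo": fit}
                    for names, fit in selector.ranking_
                ],
                "best": {
                    "descriptors": list(selector.best_model_.feature_names_in_),
                    "intercept": selector.best_model_.intercept_,
                    "coef": selector.best_model_.coef_.tolist(),
                    "std_coef": selector.best_model_.std_coef_.tolist(),
                },
            },
            indent=1,
        )
    )

    stage("refit published descriptor triple and validate")
    triple = ["C-026", "RDF035p", "HATS8p"]
    X_tr = desc.loc[nos[train_mask], triple]
    X_ext = desc.loc[nos[test_mask], triple]
    refit = DescriptorMLR().fit(X_tr, y[train_mask])
    vr = build_validation_report(
        refit,
        X_tr,
        y[train_mask],
        X_ext,
        y[test_mask],
        ids_train=list(nos[train_mask]),
        ids_ext=list(nos[test_mask]),
        n_scramble=config.n_scramble,
        seed=config.seed,
    )
    (out / "validation.json").write_text(json.dumps(vr.to_dict(), indent=1))
    pd.Series(vr.stats).to_csv(out / "statistics.csv", header=["value"])
    pd.DataFrame(
        {
            "no": vr.williams.ids,
            "leverage": vr.williams.leverage,
            "std_residual": vr.williams.std_residual,
            "outlier": [i in vr.williams.outliers for i in vr.williams.ids],
            "out_of_domain": [
                i in vr.williams.out_of_domain for i in vr.williams.ids
            ],
        }
    ).to_csv(out / "williams.csv", index=False)

    stage("predictions")
    pred_rows = []
    for rec in modeled:
        row_desc = desc.loc[rec.no]
        published = predict_published(
            row_desc["C-026"], row_desc["RDF035p"], row_desc["HATS8p"], "eq2"
        )
        pred_rows.append(
            {
                "no": rec.no,
                "mol_id": rec.mol_id,
                "split": "test" if rec.no in set(nos[test_mask]) else (
                    "excluded" if (config.exclude_outlier and rec.excluded_model2)
                    else "train"
                ),
                "log_lox": rec.log_lox,
                "published_eq2": round(published, 2),
                "published_eq2_table": rec.calc_log_lox,
                "refit_pred": round(
                    float(refit.predict(row_desc[triple].to_numpy()[None, :])[0]), 2
                ),
            }
        )
    pd.DataFrame(pred_rows).to_csv(out / "predictions.csv", index=False)

    stage("done")
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=1))
    (out / "run.log").write_text("\n".join(log) + "\n")
    return {
        "records": records,
        "descriptors": desc,
        "filtered": desc_f,
        "filter_report": report,
        "selector": selector,
        "refit_model": refit,
        "validation": vr,
        "predictions": pd.DataFrame(pred_rows),
        "output_dir": out,
    }
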