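"""End-to-end benchmark: simulate -> build datasets -> encode -> train -> evaluate.

Runs the full ratio sweep the evaluation protocol prescribes: one
synthetic proteome and network, ratio-controlled train/test datasets over
several repetitions, significance-vector encoding, RVKDE training with
cross-validated hyperparameters, and repetition-aggregated metric panels
per ratio alongside the trivial baselines.  All randomness derives from
one seed; outputs are byte-reproducible.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import evaluation
from .datasets import build_ratio_datasets, write_build_manifest, write_ratio_dataset
from .encoding import encode_proteins, pair_matrix
from .io import derive_seed
from .rvkde import DEFAULT_GRID, decision_score, fit_classifier, grid_search
from .synthetic import SyntheticConfig, generate_network, generate_proteome

logger = logging.getLogger(__name__)


@dataclass
class BenchmarkResult:
    table: pd.DataFrame          # one row per (repetition, ratio)
    summary: dict                # per-ratio aggregated metrics + baselines
    params: dict                 # hyperparameters used


def _evaluate_split(model, X_test, y_test) -> evaluation.MetricPanel:
    scores = decision_score(model, X_test)
    return evaluation.compute_metrics(
        evaluation.confusion_counts(y_test, scores > 0)
    )


def run_benchmark(
    cfg: SyntheticConfig,
    *,
    ratios: Sequence[int] = (1, 3, 7, 15),
    split: tuple[int, int] = (300, 100),
    repetitions: int = 5,
    n_permutations: int = 1_000,
    grid: Mapping[str, Sequence] | None = None,
    params: Mapping[str, float] | None = None,
    folds: int = 5,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> BenchmarkResult:
    """Run the ratio sweep and aggregate metrics over repetitions.

    Hyperparameters are either supplied (``params``) or selected once by
    grid search on the most balanced ratio's training set of the first
    repetition, then reused across ratios and repetitions.  When
    ``out_dir`` is given, datasets, per-repetition metrics, the summary
    and a manifest are written deterministically.
    """
    proteome = generate_proteome(cfg)
    positives = generate_network(cfg, proteome)
    proteins = [pid for pid, _ in proteome]
    logger.info("simulated %d proteins, %d interactions", len(proteome),
                len(positives))

    features = encode_proteins(
        proteome, feature="significance", n_permutations=n_permutations,
        seed=derive_seed(seed, "encode"),
    )
    datasets = build_ratio_datasets(
        positives, proteins, positives,
        ratios=ratios, split=split, repetitions=repetitions,
        seed=derive_seed(seed, "data"),
    )

    def matrices(ds):
        X_tr = pair_matrix(list(ds.train_pos) + list(ds.train_neg), features)
        y_tr = np.r_[np.ones(len(ds.train_pos), bool),
                     np.zeros(len(ds.train_neg), bool)]
        X_te = pair_matrix(list(ds.test_pos) + list(ds.test_neg), features)
        y_te = np.r_[np.ones(len(ds.test_pos), bool),
                     np.zeros(len(ds.test_neg), bool)]
        return X_tr, y_tr, X_te, y_te

    if params is None:
        base = min(datasets, key=lambda d: (d.ratio, d.repetition))
        X_tr, y_tr, _, _ = matrices(base)
        result = grid_search(X_tr, y_tr, grid or DEFAULT_GRID, folds=folds,
                             seed=derive_seed(seed, "grid"))
        params = result.best_params
        logger.info("grid search selected %s (CV F-measure %.3f)", params,
                    result.best_score)
    params = dict(params)

    rows = []
    panels: dict[int, list[evaluation.MetricPanel]] = {}
    for ds in datasets:
        X_tr, y_tr, X_te, y_te = matrices(ds)
        model = fit_classifier(
            X_tr[y_tr], X_tr[~y_tr],
            alpha=params["alpha"], beta=params["beta"],
            ks=int(params["ks"]), kt=int(params["kt"]),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            panel = _evaluate_split(model, X_te, y_te)
        panels.setdefault(ds.ratio, []).append(panel)
        opp_neg = evaluation.compute_metrics(evaluation.confusion_counts(
            y_te, evaluation.baseline_predict("opportunistic_neg", len(y_te))))
        rnd = evaluation.compute_metrics(evaluation.confusion_counts(
            y_te, evaluation.baseline_predict(
                "random", len(y_te),
                seed=derive_seed(seed, "baseline", ds.repetition, ds.ratio))))
        rows.append({
            "repetition": ds.repetition,
            "ratio": ds.ratio,
            **{k: round(v, 6) if v == v else float("nan")
               for k, v in panel.as_dict().items()},
            "baseline_opportunistic_neg_accuracy": round(opp_neg.accuracy, 6),
            "baseline_random_f_measure": round(rnd.f_measure, 6),
        })
        logger.info("rep %d ratio 1:%d F-measure %.3f", ds.repetition,
                    ds.ratio, panel.f_measure)

    table = pd.DataFrame(rows).sort_values(["ratio", "repetition"],
                                           ignore_index=True)
    summary: dict = {"params": params, "ratios": {}}
    for r in sorted(panels):
        agg = evaluation.aggregate_repetitions(panels[r]) \
            if len(panels[r]) > 1 else {
                name: (getattr(panels[r][0], name) * 100, 0.0)
                for name in evaluation.METRIC_NAMES
            }
        summary["ratios"][str(r)] = {
            "metrics_pct": {k: [round(m, 3), round(s, 3)]
                            for k, (m, s) in agg.items()},
            "formatted": evaluation.format_aggregate(agg),
            "opportunistic_neg_accuracy_pct": round(
                100 * np.mean([row["baseline_opportunistic_neg_accuracy"]
                               for row in rows if row["ratio"] == r]), 3),
            "random_f_measure_pct": round(
                100 * np.mean([row["baseline_random_f_measure"]
                               for row in rows if row["ratio"] == r]), 3),
        }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        data_dir = out_dir / "datasets"
        for ds in datasets:
            write_ratio_dataset(ds, data_dir)
        write_build_manifest(datasets, data_dir, seed=derive_seed(seed, "data"))
        table.to_csv(out_dir / "per_repetition_metrics.tsv", sep="\t",
                     index=False)
        (out_dir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")
        manifest = {
            "command": "benchmark",
            "config": cfg.as_dict(),
            "ratios": list(ratios),
            "split": list(split),
            "repetitions": repetitions,
            "n_permutations": n_permutations,
            "folds": folds,
            "seed": seed,
            "params": params,
        }
        (out_dir / "benchmark_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return BenchmarkResult(table=table, summary=summary, params=params)
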