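"""Confusion matrices, accuracies, and pairwise classifier comparison.

Two fitted classifiers evaluated on the same prediction set are compared on
the 2x2 contingency table of (correct, incorrect) counts.  When every
expected cell count is at least 5 the uncorrected Pearson chi-square test
(df = 1) is used, closed form

    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d));

otherwise the two-sided Fisher exact test.  p < 0.05 is the conventional
significance level for reporting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = [
    "ConfusionResult",
    "PairwiseComparison",
    "confusion_and_accuracy",
    "compare_classifiers",
    "build_report",
]

CLASSES = (1, 2, 3)


@dataclass
class ConfusionResult:
    matrix: np.ndarray              # rows = true class, cols = predicted
    per_class_accuracy: np.ndarray  # diagonal / row sums, as percent
    overall_accuracy: float         # trace / total, as percent
    n_correct: int
    n_total: int

    def to_dict(self) -> dict:
        return {
            "matrix": self.matrix.tolist(),
            "per_class_accuracy_pct": [round(a, 1)
                                       for a in self.per_class_accuracy],
            "overall_accuracy_pct": round(self.overall_accuracy, 1),
            "n_correct": self.n_correct,
            "n_total": self.n_total,
        }


def confusion_and_accuracy(y_true, y_pred,
                           classes=CLASSES) -> ConfusionResult:
    """3x3 confusion counts plus per-class and overall accuracy (percent).

    Per-class accuracy is the share of that cultivar's samples correctly
    recalled; overall accuracy is trace / total.
    """
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    valid = set(classes)
    if not (set(y_true) <= valid and set(y_pred) <= valid):
        raise ValueError(f"labels outside {sorted(valid)}")
    mat = _sk_confusion(y_true, y_pred, labels=list(classes))
    row = mat.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(row > 0, 100.0 * np.diag(mat) / row, np.nan)
    n_total = int(mat.sum())
    n_correct = int(np.trace(mat))
    return ConfusionResult(matrix=mat, per_class_accuracy=per_class,
                           overall_accuracy=100.0 * n_correct / n_total,
                           n_correct=n_correct, n_total=n_total)


@dataclass
class PairwiseComparison:
    model_a: str
    model_b: str
    table: np.ndarray               # [[correct_a, wrong_a], [correct_b, wrong_b]]
    test: str                       # "pearson" | "fisher"
    statistic: float | None         # chi2 for pearson, None for fisher
    p_value: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["table"] = self.table.tolist()
        d["p_value"] = round(self.p_value, 3)
        return d


def pearson_chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Uncorrected Pearson chi-square on a 2x2 table, df = 1."""
    (a, b), (c, d) = np.asarray(table, dtype=float)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / denom
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def compare_classifiers(correct_a: int, correct_b: int, n: int,
                        name_a: str = "A", name_b: str = "B"
                        ) -> PairwiseComparison:
    """Compare two classifiers by their correct counts on a shared
    prediction set of size n (independent-proportions layout)."""
    if n <= 0:
        raise ValueError("prediction set must be non-empty")
    for c in (correct_a, correct_b):
        if not 0 <= c <= n:
            raise ValueError("correct counts must lie in 0..n")
    table = np.array([[correct_a, n - correct_a],
                      [correct_b, n - correct_b]], dtype=int)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if np.all(expected >= 5.0):
        chi2, p = pearson_chi2_2x2(table)
        return PairwiseComparison(name_a, name_b, table, "pearson", chi2, p)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return PairwiseComparison(name_a, name_b, table, "fisher", None, float(p))


def build_report(results: dict, out_dir: str | Path | None = None,
                 manifest: dict | None = None) -> dict:
    """Assemble Tables-2/3-style report for any number of models x regions.

    `results` maps region name -> model name -> dict with keys
    ``y_true_cal, y_pred_cal, y_true_pred, y_pred_pred`` (label vectors on
    the shared calibration and prediction splits).  Every model within a
    region must share the same true-label vectors (the common split).
    Returns the report dict; if `out_dir` is given, also writes
    ``report.json`` and per-region TSV tables, deterministically.
    """
    report = {"regions": {}, "manifest": manifest or {}}
    for region, models in results.items():
        ref_cal = ref_pred = None
        entry = {"models": {}, "comparisons": []}
        for name, r in models.items():
            if ref_cal is None:
                ref_cal = np.asarray(r["y_true_cal"])
                ref_pred = np.asarray(r["y_true_pred"])
            elif not (np.array_equal(ref_cal, r["y_true_cal"])
                      and np.array_equal(ref_pred, r["y_true_pred"])):
                raise ValueError(
                    f"{region}/{name}: models evaluated on different splits")
            entry["models"][name] = {
                "calibration": confusion_and_accuracy(
                    r["y_true_cal"], r["y_pred_cal"]).to_dict(),
                "prediction": confusion_and_accuracy(
                    r["y_true_pred"], r["y_pred_pred"]).to_dict(),
                "params": r.get("params", {}),
            }
        n = len(ref_pred) if ref_pred is not None else 0
        for name_a, name_b in combinations(models, 2):
            ca = entry["models"][name_a]["prediction"]["n_correct"]
            cb = entry["models"][name_b]["prediction"]["n_correct"]
            entry["comparisons"].append(
                compare_classifiers(ca, cb, n, name_a, name_b).to_dict())
        report["regions"][region] = entry
    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def _write_report(report: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True))
    for region, entry in report["regions"].items():
        lines = ["model\tsplit\tclass\tcorrect\ttotal\taccuracy_pct"]
        for name, m in entry["models"].items():
            for split in ("calibration", "prediction"):
                cm = np.array(m[split]["matrix"])
                for i, cls in enumerate(CLASSES):
                    lines.append(
                        f"{name}\t{split}\t{cls}\t{cm[i, i]}\t{cm[i].sum()}"
                        f"\t{m[split]['per_class_accuracy_pct'][i]}")
                lines.append(f"{name}\t{split}\ttotal\t{m[split]['n_correct']}"
                             f"\t{m[split]['n_total']}"
                             f"\t{m[split]['overall_accuracy_pct']}")
        (out_dir / f"accuracy_{region}.tsv").write_text("\n".join(lines) + "\n")
        lines = ["model_a\tmodel_b\ttest\tp_value"]
        for c in entry["comparisons"]:
            lines.append(f"{c['model_a']}\t{c['model_b']}\t{c['test']}"
                         f"\t{c['p_value']}")
        (out_dir / f"comparisons_{region}.tsv").write_text("\n".join(lines) + "\n")
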