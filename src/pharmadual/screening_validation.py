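"""Compound-level validation statistics for virtual screens.

Given a labeled test library (actives vs property-matched decoys) and a
screen's hit list, this module builds the confusion matrix and the eight
retrieval statistics used to rank candidate pharmacophore models:

    Se  = TP/(TP+FN)                 sensitivity (recall)
    Sp  = TN/(TN+FP)                 specificity
    Ya  = TP/(TP+FP)                 yield of actives (precision)
    E   = Ya / (A/N)                 enrichment over random retrieval
    Acc = (TP+TN)/N                  accuracy
    DR  = Se/Sp                      discrimination ratio
    F1  = 2TP/(2TP+FP+FN)            F1 score
    MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

A 13-model reference benchmark (39 actives, 1198 decoys) ships as a CSV
fixture; its best model by MCC is the packaged five-feature query.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "LabeledLibrary",
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "metrics",
    "table6_report",
    "load_reference_benchmark",
    "assemble_test_set",
    "round_half_up",
]


@dataclass(frozen=True)
class LabeledLibrary:
    """Compound ids with binary activity labels."""

    labels: dict  # id -> "active" | "decoy"

    def __post_init__(self):
        bad = {v for v in self.labels.values()} - {"active", "decoy"}
        if bad:
            raise ValueError(f"labels must be 'active'/'decoy', got {sorted(bad)}")
        if self.n_actives < 1 or self.n_decoys < 1:
            raise ValueError("library needs at least one active and one decoy")

    @property
    def n_actives(self) -> int:
        return sum(1 for v in self.labels.values() if v == "active")

    @property
    def n_decoys(self) -> int:
        return sum(1 for v in self.labels.values() if v == "decoy")

    @property
    def n_total(self) -> int:
        return len(self.labels)

    @property
    def actives(self) -> set:
        return {k for k, v in self.labels.items() if v == "active"}

    @property
    def decoys(self) -> set:
        return {k for k, v in self.labels.items() if v == "decoy"}

    def ratio_ok(self, min_ratio: float = 30.0) -> bool:
        """Decoy:active ratio exceeds the test-set design target (>1:30)."""
        return self.n_decoys / self.n_actives > min_ratio

    @classmethod
    def from_counts(cls, n_actives: int, n_decoys: int) -> "LabeledLibrary":
        labels = {f"active{i}": "active" for i in range(n_actives)}
        labels.update({f"decoy{i}": "decoy" for i in range(n_decoys)})
        return cls(labels)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Compound-level screen outcome counts."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        """Number of hits selected by the model (TP + FP)."""
        return self.TP + self.FP

    @property
    def n_actives(self) -> int:
        return self.TP + self.FN

    @property
    def n_decoys(self) -> int:
        return self.FP + self.TN

    @property
    def n_total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class MetricsReport:
    """The eight validation statistics; zero-denominator metrics are 0 and flagged."""

    Se: float
    Sp: float
    Ya: float
    E: float
    Acc: float
    DR: float
    F1: float
    MCC: float
    zero_denominator_flags: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            k: getattr(self, k) for k in ("Se", "Sp", "Ya", "E", "Acc", "DR", "F1", "MCC")
        }


def confusion(hits, lib: LabeledLibrary) -> ConfusionMatrix:
    """Confusion matrix of a hit id set against library labels."""
    hits = set(hits)
    unknown = hits - set(lib.labels)
    if unknown:
        raise ValueError(f"hit ids not in library: {sorted(unknown)[:5]}")
    tp = len(hits & lib.actives)
    fp = len(hits & lib.decoys)
    return ConfusionMatrix(TP=tp, FP=fp, FN=lib.n_actives - tp, TN=lib.n_decoys - fp)


def _safe_div(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Compute the eight validation statistics from a confusion matrix.

    Any statistic whose denominator vanishes is reported as 0 and listed in
    ``zero_denominator_flags`` rather than raising.
    """
    tp, fp, fn, tn = cm.TP, cm.FP, cm.FN, cm.TN
    a, n_tot = cm.n_actives, cm.n_total
    flags: list[str] = []
    se = _safe_div(tp, tp + fn, "Se", flags)
    sp = _safe_div(tn, tn + fp, "Sp", flags)
    ya = _safe_div(tp, tp + fp, "Ya", flags)
    e = _safe_div(ya * n_tot, a, "E", flags) if n_tot else 0.0
    acc = _safe_div(tp + tn, n_tot, "Acc", flags)
    dr = _safe_div(se, sp, "DR", flags)
    f1 = _safe_div(2 * tp, 2 * tp + fp + fn, "F1", flags)
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "MCC", flags)
    return MetricsReport(
        Se=se, Sp=sp, Ya=ya, E=e, Acc=acc, DR=dr, F1=f1, MCC=mcc,
        zero_denominator_flags=tuple(flags),
    )


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round half away from zero, matching printed-table conventions."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def table6_report(rows) -> pd.DataFrame:
    """Per-model metrics table with best-model selection.

    ``rows`` is an iterable of ``(name, ConfusionMatrix)``. Display values
    are rounded half-up to 3 decimals; raw values are kept in ``*_raw``
    columns. The best model has the highest MCC, ties broken by F1; the
    winner is marked in the ``best`` column.
    """
    recs = []
    for name, cm in rows:
        rep = metrics(cm)
        rec = {"model": name, "n": cm.n, "TP": cm.TP, "FP": cm.FP, "FN": cm.FN, "TN": cm.TN}
        for k, v in rep.as_dict().items():
            rec[k] = round_half_up(v, 3)
            rec[f"{k}_raw"] = v
        recs.append(rec)
    df = pd.DataFrame(recs)
    if len(df):
        best_idx = df.sort_values(
            ["MCC_raw", "F1_raw"], ascending=False, kind="stable"
        ).index[0]
        df["best"] = False
        df.loc[best_idx, "best"] = True
    return df


def load_reference_benchmark() -> pd.DataFrame:
    """Load the packaged 13-model reference confusion matrices (A=39, D=1198)."""
    with resources.files("pharmadual.data").joinpath("reference_models_confusion.csv").open() as fh:
        return pd.read_csv(fh)


def assemble_test_set(
    actives: pd.DataFrame,
    decoys: pd.DataFrame,
    mw_range: tuple[float, float] = (350.0, 500.0),
    ic50_max_um: float = 10.0,
    n_decoys: int | None = None,
    seed: int = 0,
) -> tuple[LabeledLibrary, pd.DataFrame]:
    """Filter annotated actives and subsample decoys into a labeled test set.

    Actives are kept iff ``mw_range[0] <= MW <= mw_range[1]`` (inclusive) and
    ``IC50 < ic50_max_um`` (strict). Decoys are subsampled without
    replacement with a seeded RNG to ``n_decoys`` (all kept when ``None``).
    Returns the library plus a one-row audit frame (counts and ratio); a
    decoy:active ratio <= 30 emits a warning, not an error.

    ``actives`` needs columns ``id``, ``mw``, ``ic50_um``; ``decoys`` needs ``id``.
    """
    lo, hi = mw_range
    keep = actives[(actives["mw"] >= lo) & (actives["mw"] <= hi) & (actives["ic50_um"] < ic50_max_um)]
    rng = np.random.default_rng(seed)
    dec_ids = list(decoys["id"])
    if n_decoys is not None and n_decoys < len(dec_ids):
        dec_ids = [dec_ids[i] for i in sorted(rng.choice(len(dec_ids), size=n_decoys, replace=False))]
    labels = {str(i): "active" for i in keep["id"]}
    labels.update({str(i): "decoy" for i in dec_ids})
    lib = LabeledLibrary(labels)
    ratio = lib.n_decoys / lib.n_actives
    if ratio <= 30:
        warnings.warn(
            f"decoy:active ratio {ratio:.1f} does not exceed the 1:30 design target",
            stacklevel=2,
        )
    audit = pd.DataFrame(
        [{
            "n_actives_in": len(actives),
            "n_actives_kept": lib.n_actives,
            "n_decoys_kept": lib.n_decoys,
            "ratio": ratio,
            "ratio_ok": lib.ratio_ok(),
        }]
    )
    return lib, audit
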