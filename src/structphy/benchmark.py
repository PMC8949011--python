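"""Prediction-quality benchmarking of predicted/experimental structure pairs.

For each pair the module reports the TM-score (normalised by the
experimental length, full superposition search), the Kabsch RMSD over the
shared residues, and the relative Z-error; per-protein confidence is the
mean per-residue pLDDT, with 70 as the conventional low-confidence
cut-off of structure predictors.  Set-level summaries mirror boxplot
statistics (median, mean, sample SD, quartiles, Tukey 1.5*IQR outliers).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from structphy.daliscore import elastic_score, relative_z_error, self_z
from structphy.structio import Structure
from structphy.superpose import Correspondence, kabsch, tm_score

#: conventional pLDDT threshold below which a prediction is low-confidence
PLDDT_CUTOFF = 70.0


@dataclass
class BenchmarkRecord:
    pair_id: str
    set_label: str
    tm: Optional[float] = None
    rmsd: Optional[float] = None
    z_error: Optional[float] = None
    plddt: Optional[float] = None

    @property
    def low_confidence(self) -> Optional[bool]:
        return None if self.plddt is None else bool(self.plddt < PLDDT_CUTOFF)


def _common_correspondence(pred: Structure, exp: Structure) -> Correspondence:
    """Pair residues by the intersection of author residue numbers."""
    common, ia, ib = np.intersect1d(
        exp.resnums, pred.resnums, assume_unique=False, return_indices=True
    )
    if len(common) < 3:
        raise ValueError(
            f"{pred.id}/{exp.id}: fewer than 3 residues share numbering"
        )
    order = np.argsort(ia)
    return Correspondence(np.column_stack([ia[order], ib[order]]))


def evaluate_pair(
    predicted: Structure,
    experimental: Structure,
    set_label: str = "",
    calibration="polynomial",
) -> BenchmarkRecord:
    """All similarity metrics for one predicted/experimental pair."""
    c = _common_correspondence(predicted, experimental)
    sup = tm_score(experimental, predicted, c, mode="full-search",
                   l_norm=len(experimental))
    _, _, rmsd = kabsch(
        experimental.coords[c.pairs[:, 0]], predicted.coords[c.pairs[:, 1]]
    )
    z_gt = self_z(experimental, calibration)
    z_pd = elastic_score(experimental, predicted, c, calibration).z
    zerr = relative_z_error(z_gt, z_pd).z_error
    plddt = None
    if predicted.confidence is not None:
        plddt = protein_plddt(predicted)
    return BenchmarkRecord(
        pair_id=predicted.id,
        set_label=set_label,
        tm=sup.tm_score,
        rmsd=rmsd,
        z_error=zerr,
        plddt=plddt,
    )


def protein_plddt(s: Structure) -> float:
    """Per-protein confidence: mean of the per-residue pLDDT values."""
    if s.confidence is None or len(s.confidence) == 0:
        raise ValueError(f"{s.id}: no confidence values")
    return float(np.mean(s.confidence))


def records_frame(records: Sequence[BenchmarkRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "pair_id": r.pair_id,
        "set": r.set_label,
        "tm": r.tm,
        "rmsd": r.rmsd,
        "z_error": r.z_error,
        "plddt": r.plddt,
    } for r in records])


def summarize_sets(records: Sequence[BenchmarkRecord]) -> pd.DataFrame:
    """Per-set, per-metric summary statistics (order-invariant).

    SD is the sample standard deviation (n-1) and is absent for single
    records; outliers follow the Tukey 1.5*IQR whisker rule.
    """
    df = records_frame(records)
    if df.empty:
        raise ValueError("no records")
    rows = []
    for set_label, group in df.groupby("set", sort=True):
        for metric in ("tm", "rmsd", "z_error", "plddt"):
            # sorted so every statistic is invariant to record order
            vals = np.sort(group[metric].dropna().to_numpy(dtype=float))
            if len(vals) == 0:
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            outliers = sorted(vals[(vals < lo) | (vals > hi)])
            rows.append({
                "set": set_label,
                "metric": metric,
                "n": len(vals),
                "median": med,
                "mean": vals.mean(),
                "sd": vals.std(ddof=1) if len(vals) > 1 else None,
                "q1": q1,
                "q3": q3,
                "outliers": ";".join(f"{v:.4g}" for v in outliers),
            })
    return pd.DataFrame(rows)


def boxplot_payload(summary: pd.DataFrame) -> dict:
    """JSON-ready boxplot payload (whiskers at Tukey 1.5*IQR)."""
    payload = {}
    for _, row in summary.iterrows():
        payload.setdefault(row["set"], {})[row["metric"]] = {
            "median": row["median"],
            "q1": row["q1"],
            "q3": row["q3"],
            "whisker_low": row["q1"] - 1.5 * (row["q3"] - row["q1"]),
            "whisker_high": row["q3"] + 1.5 * (row["q3"] - row["q1"]),
            "outliers": [float(v) for v in row["outliers"].split(";") if v],
            "n": int(row["n"]),
        }
    return payload
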