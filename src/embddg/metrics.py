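"""Scoring indices for ddG prediction and Total/Direct/Reverse reports.

Five indices are reported, following common practice in the stability-
prediction literature: Pearson correlation (PCC), RMSE and MAE between
experimental and predicted ddG, each computed over all variations
("Total"), only direct variations, and only reverse variations; plus two
antisymmetry statistics over paired direct/reverse predictions:

* ``r_d-r``: Pearson correlation between direct and reverse predictions
  (-1 for a perfectly antisymmetric predictor);
* the antisymmetry bias ``delta = sum_i (p_dir_i + p_inv_i) / (2N)``,
  the (halved) mean deviation from p_inv = -p_dir; 0 iff the predictor is
  antisymmetric on the evaluated pairs, signed so that a systematic shift
  keeps its direction.

Experimental ddG for a reverse variation is, by thermodynamic
reversibility, the negated direct value. Correlations on degenerate
(zero-variance) inputs are reported as missing (None), never coerced to 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np


def _check_pair(e, p, min_n: int = 1) -> tuple[np.ndarray, np.ndarray]:
    e = np.asarray(e, dtype=np.float64).ravel()
    p = np.asarray(p, dtype=np.float64).ravel()
    if e.shape != p.shape:
        raise ValueError(f"length mismatch: {e.shape[0]} vs {p.shape[0]}")
    if e.shape[0] < min_n:
        raise ValueError(f"need at least {min_n} values, got {e.shape[0]}")
    return e, p


def pcc(e: Sequence[float], p: Sequence[float]) -> float:
    """Pearson correlation; raises on zero variance (undefined, not 0)."""
    e, p = _check_pair(e, p, min_n=2)
    se, sp = e.std(), p.std()
    if se == 0.0 or sp == 0.0:
        raise ZeroDivisionError(
            "Pearson correlation undefined: zero variance in "
            + ("experimental" if se == 0.0 else "predicted") + " values"
        )
    return float(np.corrcoef(e, p)[0, 1])


def rmse(e: Sequence[float], p: Sequence[float]) -> float:
    """Root mean square error, kcal/mol."""
    e, p = _check_pair(e, p)
    return float(np.sqrt(np.mean((e - p) ** 2)))


def mae(e: Sequence[float], p: Sequence[float]) -> float:
    """Mean absolute error, kcal/mol."""
    e, p = _check_pair(e, p)
    return float(np.mean(np.abs(e - p)))


def rd_r(pdir: Sequence[float], pinv: Sequence[float]) -> float:
    """Pearson correlation between paired direct and reverse predictions."""
    return pcc(pdir, pinv)


def delta_bias(pdir: Sequence[float], pinv: Sequence[float]) -> float:
    """Antisymmetry bias: mean of (p_dir + p_inv) over pairs, halved.

    Exactly 0 when p_inv = -p_dir for every pair; signed (a predictor that
    systematically overshoots in one direction keeps its sign).
    """
    pdir, pinv = _check_pair(pdir, pinv)
    return float(np.sum(pdir + pinv) / (2 * pdir.shape[0]))


def mse(y: Sequence[float], y_hat: Sequence[float]) -> float:
    """Mean squared error (the training objective)."""
    y, y_hat = _check_pair(y, y_hat)
    return float(np.mean((y - y_hat) ** 2))


@dataclass
class PartitionScores:
    """PCC/RMSE/MAE on one partition; PCC is None when undefined."""

    n: int
    pcc: Optional[float]
    rmse: float
    mae: float


@dataclass
class MetricsReport:
    """Per-partition scores plus antisymmetry statistics.

    ``reverse``, ``rd_r`` and ``delta`` are None when no reverse
    predictions were supplied (missing, not zero).
    """

    total: PartitionScores
    direct: PartitionScores
    reverse: Optional[PartitionScores] = None
    rd_r: Optional[float] = None
    delta: Optional[float] = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def format_table(self) -> str:
        """Text table with Total / Direct / Reverse / Symmetry blocks."""
        def fmt(x, width=6):
            return f"{x:{width}.2f}" if x is not None else " " * (width - 2) + "--"

        lines = [
            f"{'':10s}  {'PCC':>6s} {'RMSE':>6s} {'MAE':>6s}   n",
        ]
        blocks = [("Total", self.total), ("Direct", self.direct),
                  ("Reverse", self.reverse)]
        for label, part in blocks:
            if part is None:
                lines.append(f"{label:10s}  {'--':>6s} {'--':>6s} {'--':>6s}   --")
            else:
                lines.append(
                    f"{label:10s}  {fmt(part.pcc)} {fmt(part.rmse)} "
                    f"{fmt(part.mae)}   {part.n}"
                )
        lines.append(
            f"{'Symmetry':10s}  r_d-r={fmt(self.rd_r, 6).strip()} "
            f"delta={fmt(self.delta, 6).strip()}"
        )
        return "\n".join(lines)


def _partition(e: np.ndarray, p: np.ndarray) -> PartitionScores:
    try:
        c = pcc(e, p)
    except (ZeroDivisionError, ValueError):
        c = None
    return PartitionScores(n=int(e.shape[0]), pcc=c, rmse=rmse(e, p), mae=mae(e, p))


def evaluate(
    e_direct: Sequence[float],
    p_direct: Sequence[float],
    p_reverse: Optional[Sequence[float]] = None,
) -> MetricsReport:
    """Build the full Total/Direct/Reverse report.

    ``e_direct`` are experimental direct ddG values; reverse ground truth
    is their negation. When ``p_reverse`` (predictions for the paired
    reverse variations, aligned index-by-index with the direct ones) is
    absent, the Reverse and Symmetry entries are reported missing.
    """
    e_direct, p_direct = _check_pair(e_direct, p_direct)
    direct = _partition(e_direct, p_direct)
    if p_reverse is None:
        return MetricsReport(total=direct, direct=direct)
    _, p_reverse = _check_pair(e_direct, p_reverse)
    e_reverse = -e_direct
    e_total = np.concatenate([e_direct, e_reverse])
    p_total = np.concatenate([p_direct, p_reverse])
    return MetricsReport(
        total=_partition(e_total, p_total),
        direct=direct,
        reverse=_partition(e_reverse, p_reverse),
        rd_r=_maybe_pcc(p_direct, p_reverse),
        delta=delta_bias(p_direct, p_reverse),
    )


def _maybe_pcc(a: np.ndarray, b: np.ndarray) -> Optional[float]:
    try:
        return pcc(a, b)
    except (ZeroDivisionError, ValueError):
        return None
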