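"""Scoring-power evaluation statistics (CASF conventions).

For predicted x and experimental y (both in pKd units):

    R    Pearson correlation coefficient
    MAE  mean |x_i - y_i|
    RMSE sqrt(mean (x_i - y_i)^2)
    SD   sqrt( sum c_i^2 / (N - 1) ),  c_i = (a*x_i + b) - y_i

with (a, b) the least-squares line regressing the experimental values on the
predictions (the CASF orientation), so SD measures scatter about the best
linear recalibration of the predictions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np


@dataclass
class EvalReport:
    r: float
    mae: float
    rmse: float
    sd: float
    n: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def format_table(self) -> str:
        rows = [("N", f"{self.n}"), ("R", f"{self.r:.4f}"),
                ("MAE", f"{self.mae:.4f}"), ("RMSE", f"{self.rmse:.4f}"),
                ("SD", f"{self.sd:.4f}")]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


def evaluate(predicted, experimental) -> EvalReport:
    """Compute R / MAE / RMSE / SD for aligned prediction vectors."""
    x = np.asarray(predicted, dtype=np.float64)
    y = np.asarray(experimental, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("predicted and experimental must be equal-length 1-D")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if np.var(x) == 0.0 or np.var(y) == 0.0:
        raise ValueError("constant vector: correlation undefined")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    diff = x - y
    mae = float(np.mean(np.abs(diff)))
    rmse = float(np.sqrt(np.mean(diff ** 2)))
    a = float(np.dot(xc, yc) / np.dot(xc, xc))
    b = float(y.mean() - a * x.mean())
    c = (a * x + b) - y
    sd = float(np.sqrt(np.dot(c, c) / (n - 1)))
    return EvalReport(r=r, mae=mae, rmse=rmse, sd=sd, n=n)
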