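"""Response to density (RD) via the conditional-variable method.

RD is the high-density phenotype with its linear dependence on the
normal-density phenotype removed:

    RD_line = x_D2 - (C_D1D2 / V_D1) * (x_D1 - mean(x_D1))

so that, by construction, cov(RD, x_D1) = 0 and mean(RD) = mean(x_D2).
RD is exactly the intercept-plus-residual of the OLS regression of x_D2 on
x_D1, i.e. the part of density-2 performance not predictable from the
line's density-1 performance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RDResult", "response_to_density", "rd_table"]

_DEGENERATE_VAR = 1e-12


@dataclass
class RDResult:
    rd: np.ndarray  # per-line RD values, node-count units
    slope: float  # b = C_D1D2 / V_D1
    mean_d1: float
    var_d1: float
    cov_d1d2: float
    n: int
    degenerate: bool = False


def response_to_density(x_d1, x_d2) -> RDResult:
    """Per-line RD from paired replicate means under the two densities.

    Covariance and variance use the sample (n-1) convention; the n-1 factor
    cancels in the slope.  A degenerate x_D1 (variance below 1e-12) returns
    RD = x_D2 with a warning — the covariance is then 0 as well, so the
    regression adjustment vanishes.
    """
    x1 = np.asarray(x_d1, dtype=float)
    x2 = np.asarray(x_d2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("x_D1 and x_D2 must be 1-d arrays of equal length")
    if x1.size < 3:
        raise ValueError("need at least 3 complete line pairs")
    mean1 = float(x1.mean())
    v1 = float(np.var(x1, ddof=1))
    c12 = float(np.cov(x1, x2, ddof=1)[0, 1])
    if v1 < _DEGENERATE_VAR:
        warnings.warn("x_D1 has (near) zero variance; RD falls back to x_D2")
        return RDResult(rd=x2.copy(), slope=np.nan, mean_d1=mean1, var_d1=v1,
                        cov_d1d2=c12, n=x1.size, degenerate=True)
    b = c12 / v1
    return RDResult(rd=x2 - b * (x1 - mean1), slope=b, mean_d1=mean1,
                    var_d1=v1, cov_d1d2=c12, n=x1.size)


def rd_table(pheno: pd.DataFrame, d1: str = "D1", d2: str = "D2") -> pd.DataFrame:
    """RD per environment from a long phenotype table.

    Replicates are averaged per (line, env, density) first; lines missing
    either density within an environment are dropped (complete case, count
    kept in the ``n_dropped`` attr).  Returns (line, env, RD).
    """
    lm = (pheno.groupby(["env", "density", "line"], sort=False)["value"]
          .mean().unstack("density"))
    rows, dropped = [], 0
    for env, g in lm.groupby(level="env", sort=True):
        g = g.droplevel("env")
        complete = g[[d1, d2]].dropna()
        dropped += len(g) - len(complete)
        res = response_to_density(complete[d1].to_numpy(), complete[d2].to_numpy())
        rows.append(pd.DataFrame({"line": complete.index, "env": env, "RD": res.rd}))
    out = pd.concat(rows, ignore_index=True)
    out.attrs["n_dropped"] = dropped
    return out
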