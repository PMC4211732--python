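"""AICc ranking, Akaike weights and the 12-model detection family.

The effective sample size for the small-sample correction is the number
of distinct individuals detected, which is the convention under which the
ranking arithmetic of SCR model tables is reproduced exactly.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .detection import ModelSpec
from .io import CaptureData, TrapArray
from .likelihood import FitResult, fit_scr
from .spatial import HabitatMask

__all__ = ["aicc", "model_table", "run_model_family", "MODEL_FAMILY"]

# the canonical 12-model a priori family: each g0 structure crossed with
# sigma constant or sex-specific; behaviour and time are never combined
MODEL_FAMILY: tuple[ModelSpec, ...] = tuple(
    ModelSpec(g0_terms=g0, sigma_terms=sig)
    for g0 in (
        ("intercept",),
        ("intercept", "t"),
        ("intercept", "b"),
        ("intercept", "bk"),
        ("intercept", "Bk"),
        ("intercept", "sex"),
    )
    for sig in (("intercept",), ("intercept", "sex"))
)


def aicc(lnL: float, K: int, n: int) -> float:
    """Akaike's information criterion with small-sample correction.

    ``-2 lnL + 2K + 2K(K+1)/(n - K - 1)`` with ``n`` the number of
    detected individuals.  Undefined (raises) when ``n <= K + 1``.
    """
    if K < 0:
        raise ValueError("K must be non-negative")
    if K > 0 and n <= K + 1:
        raise ValueError(f"AICc undefined for n={n} <= K+1={K + 1}")
    base = -2.0 * lnL + 2.0 * K
    if K == 0:
        return base
    return base + 2.0 * K * (K + 1) / (n - K - 1)


Entry = Union[FitResult, tuple]


def model_table(
    fits: Sequence[Entry],
    n: Optional[int] = None,
    competing_delta: float = 2.0,
) -> pd.DataFrame:
    """Rank models by AICc with delta-AICc and Akaike weights.

    ``fits`` may be :class:`FitResult` objects (all sharing the same data,
    hence the same ``n``) or ``(name, lnL, K)`` tuples with ``n`` given
    explicitly.  Models within ``competing_delta`` AICc units of the best
    are flagged as competing.
    """
    if not fits:
        raise ValueError("need at least one model")
    rows = []
    for f in fits:
        if isinstance(f, FitResult):
            if n is None:
                n = f.n
            elif f.n != n:
                raise ValueError(
                    f"fits disagree on number of individuals ({f.n} vs {n})"
                )
            rows.append({"model": f.name, "K": f.K_params, "lnL": f.lnL})
        else:
            name, lnL, K = f
            rows.append({"model": name, "K": int(K), "lnL": float(lnL)})
    if n is None:
        raise ValueError("n (individuals detected) required for tuple entries")
    df = pd.DataFrame(rows)
    df["AICc"] = [aicc(r.lnL, r.K, n) for r in df.itertuples()]
    df = df.sort_values("AICc", kind="stable").reset_index(drop=True)
    df["dAICc"] = df["AICc"] - df["AICc"].iloc[0]
    rel = np.exp(-0.5 * df["dAICc"].to_numpy())
    df["weight"] = rel / rel.sum()
    df["competing"] = df["dAICc"] <= competing_delta
    return df


def run_model_family(
    data: CaptureData,
    traps: TrapArray,
    mask: HabitatMask,
    specs: Sequence[ModelSpec] = MODEL_FAMILY,
) -> tuple[pd.DataFrame, dict]:
    """Fit every model of the family and rank the converged ones by AICc.

    Individual fit failures are recorded (and excluded from the weights)
    rather than aborting the run.  Returns the ranked table and a mapping
    model name -> FitResult (or the exception that killed the fit).
    """
    fits: dict = {}
    ok: list[FitResult] = []
    for spec in specs:
        try:
            fit = fit_scr(spec, data, traps, mask)
        except Exception as exc:  # noqa: BLE001 - per-model isolation
            warnings.warn(f"model {spec.name} failed: {exc}")
            fits[spec.name] = exc
            continue
        fits[spec.name] = fit
        if fit.converged:
            ok.append(fit)
        else:
            warnings.warn(f"model {spec.name} did not converge; excluded from table")
    if not ok:
        raise RuntimeError("no model converged")
    return model_table(ok), fits
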