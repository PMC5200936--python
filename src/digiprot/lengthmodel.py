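"""Protein length as a function of exon architecture.

Across eukaryotic species, mean protein length (Y, aa) is predicted almost
perfectly from mean exon number (EN) and mean exon length (EL, nt) once the
interaction term is included, because protein length is, up to the stop
codon, EN * EL / 3.  The species-level hyperplane fit published for the
492-species survey is

    Y = -1.03 + 0.000034 * EL + 0.34 * EN + 0.33 * EL * EN

with R^2 ~ 1.  This module fits that ordinary-least-squares model on any
table of (mean_pl, mean_en, mean_el) rows, evaluates a fitted or published
hyperplane at given (EN, EL), computes the rounded percentage contrasts used
when comparing lineages, and summarises domain-count tables (histogram of
domains per protein and the OLS slope of length on domain count).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class HyperplaneModel:
    intercept: float
    beta_el: float  # aa per nt
    beta_en: float  # aa per exon
    beta_interaction: float  # aa per nt*exon; 0.0 when the term is absent
    r_squared: float
    n_obs: int
    pvalues: dict[str, float] | None = None

    def predict(self, en: float, el: float) -> float:
        return evaluate_hyperplane(self, en, el)


class RankDeficientDesignError(ValueError):
    pass


def fit_length_model(
    rows: pd.DataFrame, interaction: bool = True
) -> HyperplaneModel:
    """OLS fit of mean protein length on mean exon number and exon length.

    ``rows`` needs columns ``mean_pl``, ``mean_en``, ``mean_el`` (one row per
    species, or per group for a coarse check).  With ``interaction`` the
    EN*EL product joins the design.
    """
    required = {"mean_pl", "mean_en", "mean_el"}
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    y = rows["mean_pl"].to_numpy(dtype=float)
    X = pd.DataFrame(
        {
            "EL": rows["mean_el"].to_numpy(dtype=float),
            "EN": rows["mean_en"].to_numpy(dtype=float),
        }
    )
    if interaction:
        X["EL_x_EN"] = X["EL"] * X["EN"]
    X = sm.add_constant(X, prepend=True)
    if len(rows) < X.shape[1]:
        raise RankDeficientDesignError(
            f"{len(rows)} rows cannot identify {X.shape[1]} coefficients"
        )
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise RankDeficientDesignError("collinear design matrix")
    fit = sm.OLS(y, X).fit()
    params = fit.params
    return HyperplaneModel(
        intercept=float(params["const"]),
        beta_el=float(params["EL"]),
        beta_en=float(params["EN"]),
        beta_interaction=float(params["EL_x_EN"]) if interaction else 0.0,
        r_squared=float(fit.rsquared),
        n_obs=int(fit.nobs),
        pvalues={k: float(v) for k, v in fit.pvalues.items()},
    )


#: Published species-level hyperplane coefficients (492-species survey).
PUBLISHED_HYPERPLANE = HyperplaneModel(
    intercept=-1.03,
    beta_el=0.000034,
    beta_en=0.34,
    beta_interaction=0.33,
    r_squared=float("nan"),
    n_obs=492,
)


def evaluate_hyperplane(
    model: HyperplaneModel | Mapping[str, float], en: float, el: float
) -> float:
    """Predicted protein length (aa) at mean exon number EN and length EL."""
    if en < 0 or el < 0:
        raise ValueError("EN and EL must be non-negative")
    if isinstance(model, Mapping):
        model = HyperplaneModel(
            intercept=model["intercept"],
            beta_el=model["beta_el"],
            beta_en=model["beta_en"],
            beta_interaction=model.get("beta_interaction", 0.0),
            r_squared=float("nan"),
            n_obs=0,
        )
    return (
        model.intercept
        + model.beta_el * el
        + model.beta_en * en
        + model.beta_interaction * el * en
    )


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def percent_difference(
    a: float, b: float, mode: Literal["more", "fewer", "larger", "smaller"]
) -> int:
    """Rounded integer percentage contrast of ``a`` against reference ``b``.

    ``more``/``larger`` report 100*(a-b)/b; ``fewer``/``smaller`` report
    100*(b-a)/b.  Rounding is to the nearest integer, half away from zero.
    """
    if b <= 0:
        raise ValueError("reference value must be positive")
    if mode in ("more", "larger"):
        pct = 100.0 * (a - b) / b
    elif mode in ("fewer", "smaller"):
        pct = 100.0 * (b - a) / b
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return _round_half_away(pct)


@dataclass
class DomainStats:
    histogram: dict[int, float]  # domain count -> relative frequency
    tail_fractions: dict[int, float]  # k -> fraction of proteins with >= k domains
    slope_aa_per_domain: float | None
    intercept_aa: float | None
    n: int


def domain_stats(
    table: pd.DataFrame,
    tail_ks: tuple[int, ...] = (4, 8),
) -> DomainStats:
    """Histogram and tail fractions of domains per protein; OLS of length on
    domain count when lengths are present.

    ``table`` needs a ``domain_count`` column and optionally ``protein_aa``.
    The slope estimates how many residues each additional domain adds.
    """
    if table.empty:
        raise ValueError("empty domain table")
    counts = table["domain_count"].to_numpy(dtype=int)
    if np.any(counts < 0):
        raise ValueError("domain counts must be non-negative")
    n = counts.size
    values, freqs = np.unique(counts, return_counts=True)
    histogram = {int(v): float(c) / n for v, c in zip(values, freqs)}
    tails = {int(k): float(np.mean(counts >= k)) for k in tail_ks}

    slope = intercept = None
    if "protein_aa" in table.columns and table["protein_aa"].notna().all():
        if np.unique(counts).size < 2:
            slope = intercept = None  # degenerate: slope undefined
        else:
            X = sm.add_constant(counts.astype(float))
            fit = sm.OLS(table["protein_aa"].to_numpy(dtype=float), X).fit()
            intercept = float(fit.params[0])
            slope = float(fit.params[1])
    return DomainStats(
        histogram=histogram,
        tail_fractions=tails,
        slope_aa_per_domain=slope,
        intercept_aa=intercept,
        n=n,
    )
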