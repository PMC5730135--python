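"""Reliability and correlation analysis of area displacement measurements.

Covers the statistical layer of the study: intra-rater repeatability of the
area measurements across two sessions (two-way absolute-agreement ICC with a
paired-difference report), per-area descriptive statistics, and Spearman
rank correlation matrices relating hard- and soft-tissue displacements,
split into maxillary and mandibular area sets.

The ICC model is ICC(A,1) in McGraw & Wong's nomenclature: two-way, single
measurement, absolute agreement — one operator measured everything twice and
a systematic offset between sessions should count against reliability.  The
model tag is carried on every result.  With eight subjects the asymptotic
Spearman p-value is poor, so for n <= 9 the two-sided p is computed by exact
enumeration of all n! rank permutations; larger samples fall back to the
t approximation, and the switch is recorded on the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

#: area sets of the two correlation matrices
MAXILLARY_AREAS = ("Nasal Tip", "Soft A Point", "A Point", "Upper Lip",
                   "Upper Incisors", "Left Cheilion", "Right Cheilion",
                   "Left Supra Cheilion", "Right Supra Cheilion")
MANDIBULAR_AREAS = ("Left Sub Cheilion", "Right Sub Cheilion", "Lower Lip",
                    "Lower Incisors", "Soft Pogonion", "Pogonion")

EXACT_PERMUTATION_MAX_N = 9


# --------------------------------------------------------------------------
# intraclass correlation
# --------------------------------------------------------------------------

@dataclass
class ICCResult:
    icc: float
    model_tag: str
    n: int
    ci95: tuple[float, float]

    def __repr__(self) -> str:
        lo, hi = self.ci95
        return (f"{self.model_tag} = {self.icc:.4f} "
                f"(95% CI {lo:.4f} to {hi:.4f}, n = {self.n})")


def icc_repeatability(session1, session2, alpha: float = 0.05) -> ICCResult:
    """Two-way absolute-agreement single-measurement ICC of two sessions.

    Computed from the two-way ANOVA mean squares (rows = subjects, columns =
    sessions) with the McGraw & Wong F-based confidence interval.  Duplicated
    sessions give ICC exactly 1; zero between-subject variance in both
    sessions is undefined and raises.
    """
    x = np.asarray(session1, dtype=float).ravel()
    y = np.asarray(session2, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("sessions must be paired")
    n = len(x)
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    if np.allclose(row_means, row_means[0], atol=1e-300) and \
            np.allclose(data.std(axis=0), 0.0):
        raise ValueError("zero variance across subjects in both sessions; "
                         "ICC is undefined")
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)          # rows
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)          # columns
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))                               # residual
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("ICC denominator is zero; data are degenerate")
    icc = (msr - mse) / denom

    if mse == 0 and msc == 0:
        ci = (1.0, 1.0)  # perfect agreement; the F interval degenerates
    else:
        # McGraw & Wong (1996) interval for ICC(A,1)
        a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
        b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
        v_num = (a * msc + b * mse) ** 2
        v_den = ((a * msc) ** 2 / (k - 1)
                 + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        v = v_num / v_den if np.isfinite(v_num) and v_den > 0 else n - 1
        f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lo = (n * (msr - f_l * mse)
              / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr))
        hi = (n * (f_u * msr - mse)
              / (k * msc + (k * n - k - n) * mse + n * f_u * msr))
        ci = (float(min(lo, 1.0)), float(min(hi, 1.0)))
    return ICCResult(icc=float(icc), model_tag="ICC(A,1)", n=n,
                     ci95=(min(ci[0], float(icc)), max(ci[1], float(icc))))


def difference_report(session1: pd.DataFrame,
                      session2: pd.DataFrame) -> pd.DataFrame:
    """Per-area Min/Max/Mean/SD of session differences with 95% t-CI.

    The CI of the mean difference is ``mean ± t(n-1, 0.975) * SD / sqrt(n)``.
    """
    if session1.shape != session2.shape or \
            list(session1.columns) != list(session2.columns):
        raise ValueError("sessions must share subjects and areas")
    n = len(session1)
    if n < 2:
        raise ValueError("difference report needs at least 2 subjects")
    diff = session2.to_numpy(dtype=float) - session1.to_numpy(dtype=float)
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    half = sps.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
    return pd.DataFrame({"Min": diff.min(axis=0), "Max": diff.max(axis=0),
                         "Mean": mean, "SD": sd,
                         "CI95_low": mean - half, "CI95_high": mean + half},
                        index=session1.columns)


def descriptives(table: pd.DataFrame) -> pd.DataFrame:
    """Per-area Min/Max/Mean/SD (sample SD, n-1; empty for a single subject)."""
    if len(table) < 1:
        raise ValueError("need at least one subject")
    vals = table.to_numpy(dtype=float)
    sd = vals.std(axis=0, ddof=1) if len(table) > 1 \
        else np.full(vals.shape[1], np.nan)
    return pd.DataFrame({"Min": vals.min(axis=0), "Max": vals.max(axis=0),
                         "Mean": vals.mean(axis=0), "SD": sd},
                        index=table.columns)


# --------------------------------------------------------------------------
# Spearman correlation with exact small-n permutation p
# --------------------------------------------------------------------------

@dataclass
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    method: str  # "exact-permutation" or "t-approximation"


@lru_cache(maxsize=8)
def _permutation_matrix(n: int) -> np.ndarray:
    return np.array(list(permutations(range(n))), dtype=np.int64)


@lru_cache(maxsize=8)
def _null_abs_rho_sorted(n: int) -> np.ndarray:
    """Sorted |rho| over all permutations of tie-free ranks (cacheable)."""
    r = np.arange(n, dtype=float)
    rc = (r - r.mean()) / np.sqrt(np.sum((r - r.mean()) ** 2))
    perm = rc[_permutation_matrix(n)]
    return np.sort(np.abs(perm @ rc))


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman(x, y) -> SpearmanResult:
    """Spearman rho with a two-sided p-value.

    Average ranks for ties.  For n <= 9 the p-value is exact: the fraction
    of all n! permutations of one rank vector whose |rho| reaches the
    observed |rho|.  Larger n uses the standard t approximation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("inputs must be paired")
    n = len(x)
    if n < 3:
        raise ValueError("Spearman needs at least 3 pairs")
    rx, ry = _rank(x), _rank(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero rank variance; correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_PERMUTATION_MAX_N:
        tol = 1e-12
        ties = (len(np.unique(rx)) < n) or (len(np.unique(ry)) < n)
        if not ties:
            null = _null_abs_rho_sorted(n)
            count = len(null) - np.searchsorted(null, abs(rho) - tol, "left")
            p = count / len(null)
        else:
            rxc = rx - rx.mean()
            ryc = ry - ry.mean()
            rxc /= np.sqrt(np.sum(rxc ** 2))
            ryc /= np.sqrt(np.sum(ryc ** 2))
            rhos = (ryc[_permutation_matrix(n)] @ rxc)
            p = float(np.mean(np.abs(rhos) >= abs(rho) - tol))
        return SpearmanResult(rho, float(p), n, "exact-permutation")
    res = sps.spearmanr(x, y)
    return SpearmanResult(rho, float(res.pvalue), n, "t-approximation")


# --------------------------------------------------------------------------
# correlation matrix in the lower-r / upper-p layout
# --------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    areas: tuple[str, ...]
    rho: np.ndarray          # full symmetric matrix, diagonal nan
    p: np.ndarray            # full symmetric matrix, diagonal nan
    alpha: float
    methods: dict[str, str]

    @property
    def significant(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.p < self.alpha

    def to_frame(self) -> pd.DataFrame:
        """Lower triangle rho, upper triangle p — the published layout."""
        k = len(self.areas)
        out = np.full((k, k), np.nan)
        il = np.tril_indices(k, -1)
        iu = np.triu_indices(k, 1)
        out[il] = self.rho[il]
        out[iu] = self.p[iu]
        return pd.DataFrame(out, index=self.areas, columns=self.areas)

    def render(self) -> str:
        """Plain-text table: r below the dashes, p above, '*' where p < alpha."""
        k = len(self.areas)
        cells = [["-" for _ in range(k)] for _ in range(k)]
        for i in range(k):
            for j in range(k):
                if i > j:
                    cells[i][j] = f"{self.rho[i, j]:.2f}"
                elif i < j:
                    mark = "*" if self.p[i, j] < self.alpha else ""
                    pv = self.p[i, j]
                    cells[i][j] = ("<0.01" if pv < 0.005 else f"{pv:.2f}") + mark
        width = max(len(a) for a in self.areas) + 2
        cw = 8
        lines = [" " * width + "".join(a[:cw - 1].rjust(cw) for a in self.areas)]
        for i, a in enumerate(self.areas):
            lines.append(a.ljust(width) + "".join(c.rjust(cw) for c in cells[i]))
        lines.append(f"Correlations are below and p values above the dashes; "
                     f"* marks p < {self.alpha:g}.")
        return "\n".join(lines)


_AREA_SETS = {"maxillary": MAXILLARY_AREAS, "mandibular": MANDIBULAR_AREAS}


def correlation_matrix(table: pd.DataFrame, area_set="maxillary",
                       alpha: float = 0.05) -> CorrelationMatrix:
    """Pairwise Spearman correlations of one area set across subjects.

    ``area_set`` is ``"maxillary"`` (9 areas), ``"mandibular"`` (6 areas) or
    an explicit list of column names.  No multiple-testing correction is
    applied; each cell is tested at ``alpha``.
    """
    areas = tuple(_AREA_SETS.get(area_set, area_set))
    missing = [a for a in areas if a not in table.columns]
    if missing:
        raise ValueError(f"areas missing from the table: {missing}")
    if len(table) < 3:
        raise ValueError("correlation needs at least 3 subjects")
    k = len(areas)
    rho = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    methods = {}
    for i in range(k):
        for j in range(i + 1, k):
            res = spearman(table[areas[i]], table[areas[j]])
            rho[i, j] = rho[j, i] = res.rho
            p[i, j] = p[j, i] = res.p_value
            methods[f"{areas[i]} vs {areas[j]}"] = res.method
    return CorrelationMatrix(areas=areas, rho=rho, p=p, alpha=alpha,
                             methods=methods)


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (optional; off by default in reports)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    m = len(p)
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def load_measurements(path, index_col: int = 0) -> pd.DataFrame:
    """Read a subjects x areas CSV of mean displacements (mm)."""
    df = pd.read_csv(path, index_col=index_col)
    if df.isna().any().any():
        raise ValueError("measurement table has missing cells")
    return df
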