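"""Two-group differential expression with empirical-Bayes variance moderation.

The model is the classic gene-wise two-group linear model: for gene g,
log2(count+1) values split by genotype, with

    log2FC_g = mean(mutant) − mean(control)

and the residual variance s²_g (pooled within-group, d = n1+n2−2 df) shrunk
toward a common prior:

    s̃²_g = (d0·s0² + d·s²_g) / (d0 + d)

The prior (d0, s0²) is estimated by the method of moments on the log sample
variances, using the exact moments of log χ² (digamma/trigamma), and the
moderated t statistic t̃ = log2FC / √(s̃²(1/n1+1/n2)) is referred to a t
distribution with d + d0 degrees of freedom.  Counts are library-size
scaled (counts per million) before the log transform by default, since raw
counts confound fold change with sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats

from ._errors import (
    InsufficientDataError,
    UndefinedCorrelationError,
    ValidationError,
)

GENOTYPES = ("control", "mutant")


def log_transform(counts: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(x + 1); rejects negative entries."""
    if (counts.to_numpy() < 0).any():
        raise ValidationError("count matrix contains negative values")
    return np.log2(counts + 1.0)


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million library-size scaling, per column."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValidationError("a sample has zero total counts")
    return counts * (1e6 / totals)


def validate_sample_sheet(sheet: pd.DataFrame, columns) -> pd.DataFrame:
    """Check the sheet covers every matrix column exactly once."""
    required = {"sample_id", "genotype"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
    sheet = sheet.set_index("sample_id", drop=False) if sheet.index.name != "sample_id" else sheet
    if sheet["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in sample sheet")
    cols = set(columns)
    covered = set(sheet["sample_id"])
    if not cols <= covered:
        raise ValidationError(f"samples without sheet entry: {sorted(cols - covered)}")
    bad = set(sheet.loc[sheet["sample_id"].isin(cols), "genotype"]) - set(GENOTYPES)
    if bad:
        raise ValidationError(f"unknown genotype labels: {sorted(bad)}")
    return sheet


def estimate_variance_prior(s2: np.ndarray, d: int) -> Tuple[float, float]:
    """Method-of-moments prior (d0, s0²) from gene-wise sample variances.

    Uses the exact mean/variance of log s² when s² ~ s0²·χ²_d/d scaled by a
    scaled-inverse-χ² prior: matching trigamma for d0 and digamma for s0².
    If the observed spread of log s² is no larger than the sampling spread
    trigamma(d/2), the prior is degenerate (d0 = ∞) and s0² is the pooled
    (mean) variance.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(s2.mean()) if s2.size else 0.0
    e = np.log(s2[ok])
    emean = e.mean()
    evar = e.var(ddof=1)
    target = evar - special.polygamma(1, d / 2.0)
    if target <= 0:
        return np.inf, float(s2.mean())
    half_d0 = _trigamma_inverse(target)
    d0 = 2.0 * half_d0
    log_s0 = (
        emean
        - special.digamma(d / 2.0)
        + np.log(d / 2.0)
        + special.digamma(half_d0)
        - np.log(half_d0)
    )
    return float(d0), float(np.exp(log_s0))


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        f = special.polygamma(1, x) - y
        fp = special.polygamma(2, x)
        step = f / fp
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < tol * max(1.0, x):
            return x_new
        x = x_new
    return x


class DifferentialExpression:
    """Gene-wise two-group differential expression model.

    Parameters
    ----------
    counts : DataFrame, genes × samples, non-negative
    sample_sheet : DataFrame with columns sample_id, genotype
        (``control``/``mutant``), and optionally assay, animal_id
    assay : restrict to one assay label from the sheet (optional)
    library_scale : apply counts-per-million before log2(x+1) (default True)
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        sample_sheet: pd.DataFrame,
        assay: Optional[str] = None,
        library_scale: bool = True,
    ):
        sheet = validate_sample_sheet(sample_sheet, counts.columns)
        if assay is not None:
            keep = sheet.loc[sheet["assay"] == assay, "sample_id"]
            counts = counts[[c for c in counts.columns if c in set(keep)]]
        self.sheet = sheet.loc[sheet["sample_id"].isin(counts.columns)]
        if (counts.to_numpy() < 0).any():
            raise ValidationError("count matrix contains negative values")
        self.counts = counts
        self.library_scale = library_scale
        self._groups = {
            g: list(self.sheet.loc[self.sheet["genotype"] == g, "sample_id"])
            for g in GENOTYPES
        }
        for g, cols in self._groups.items():
            if len(cols) < 2:
                raise InsufficientDataError(
                    f"genotype {g!r} has {len(cols)} samples; need at least 2"
                )

    @classmethod
    def from_tsv(
        cls, counts_path: str, sheet_path: str, assay: Optional[str] = None, **kw
    ) -> "DifferentialExpression":
        counts = read_counts_tsv(counts_path)
        sheet = pd.read_csv(sheet_path, sep="\t")
        return cls(counts, sheet, assay=assay, **kw)

    def transformed(self) -> pd.DataFrame:
        x = cpm(self.counts) if self.library_scale else self.counts
        return log_transform(x)

    def fit(
        self,
        prior_df: Optional[float] = None,
        prior_var: Optional[float] = None,
    ) -> "DEResults":
        """Fit the moderated two-group model.

        ``prior_df``/``prior_var`` override the empirical-Bayes prior; a
        ``prior_df`` of 0 reproduces the ordinary two-sample t test.
        """
        x = self.transformed()
        c_cols, m_cols = self._groups["control"], self._groups["mutant"]
        xc = x[c_cols].to_numpy(dtype=float)
        xm = x[m_cols].to_numpy(dtype=float)
        n1, n2 = xc.shape[1], xm.shape[1]
        d = n1 + n2 - 2
        mean_c, mean_m = xc.mean(axis=1), xm.mean(axis=1)
        log2fc = mean_m - mean_c
        avg_expr = x.to_numpy(dtype=float).mean(axis=1)
        ss = xc.var(axis=1, ddof=1) * (n1 - 1) + xm.var(axis=1, ddof=1) * (n2 - 1)
        s2 = ss / d
        if prior_df is None:
            d0, s0_2 = estimate_variance_prior(s2, d)
            if prior_var is not None:
                s0_2 = prior_var
        else:
            d0 = prior_df
            s0_2 = prior_var if prior_var is not None else float(np.mean(s2))
        if np.isinf(d0):
            s2_mod = np.full_like(s2, s0_2)
            df_total = np.inf
        elif d0 == 0:
            s2_mod = s2
            df_total = float(d)
        else:
            s2_mod = (d0 * s0_2 + d * s2) / (d0 + d)
            df_total = float(d0 + d)
        se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, log2fc / se, np.where(log2fc == 0, 0.0, np.inf * np.sign(log2fc)))
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        fdr = _bh_fdr(p)
        frame = pd.DataFrame(
            {
                "avg_log2_expr": avg_expr,
                "log2FC": log2fc,
                "t": t,
                "p": p,
                "fdr": fdr,
            },
            index=self.counts.index,
        )
        frame.index.name = "gene_id"
        return DEResults(frame, d0=float(d0), s0_2=float(s0_2), df_resid=d,
                         n_control=n1, n_mutant=n2)


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    finite = np.isfinite(p)
    out = np.full_like(p, np.nan, dtype=float)
    if finite.any():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


@dataclass
class DEResults:
    """Results of a :class:`DifferentialExpression` fit.

    ``frame`` carries one row per gene: avg_log2_expr, log2FC, t, p, fdr,
    and (after :meth:`classify`) a ``significant`` flag.  The raw p-value is
    what drives significance calls; the BH-FDR column is diagnostic only.
    """

    frame: pd.DataFrame
    d0: float
    s0_2: float
    df_resid: int
    n_control: int
    n_mutant: int

    def classify(
        self, fc_threshold: float = 2.0, p_threshold: float = 0.01
    ) -> Tuple[list, list]:
        """Split genes into (up, down) at |FC| > fc_threshold and p < p_threshold.

        Thresholds are strict: log2FC exactly at log2(fc_threshold) is not
        significant.
        """
        lfc_cut = np.log2(fc_threshold)
        f = self.frame
        up = f.index[(f["log2FC"] > lfc_cut) & (f["p"] < p_threshold)].tolist()
        down = f.index[(f["log2FC"] < -lfc_cut) & (f["p"] < p_threshold)].tolist()
        self.frame["significant"] = self.frame.index.isin(set(up) | set(down))
        return up, down

    def fc_expression_correlation(self) -> Tuple[float, float]:
        """Pearson correlation between log2FC and mean log2 expression."""
        return fc_expression_correlation(self.frame)

    def summary(self) -> str:
        f = self.frame
        up, down = self.classify()
        lines = [
            "Differential expression (moderated two-group t)",
            f"  genes: {len(f)}   samples: {self.n_control} control vs {self.n_mutant} mutant",
            f"  prior df d0: {self.d0:.4g}   prior variance s0^2: {self.s0_2:.4g}",
            f"  residual df: {self.df_resid}   total df: {self.d0 + self.df_resid:.4g}",
            f"  significant (|FC|>2, p<0.01): {len(up)} up, {len(down)} down",
        ]
        return "\n".join(lines)

    def to_tsv(self, path: str) -> None:
        self.classify()
        self.frame.to_csv(path, sep="\t", float_format="%.17g")


def classify_de(
    results: DEResults, fc_threshold: float = 2.0, p_threshold: float = 0.01
) -> Tuple[list, list]:
    """Functional alias for :meth:`DEResults.classify`."""
    return results.classify(fc_threshold, p_threshold)


def fc_expression_correlation(frame: pd.DataFrame) -> Tuple[float, float]:
    """Pearson r (and t-approximation p) between log2FC and mean expression.

    A negative r reproduces the diagnostic that highly expressed genes are
    preferentially downregulated.
    """
    sub = frame[["avg_log2_expr", "log2FC"]].replace([np.inf, -np.inf], np.nan).dropna()
    if len(sub) < 3:
        raise InsufficientDataError("need at least 3 genes with finite values")
    x = sub["avg_log2_expr"].to_numpy()
    y = sub["log2FC"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in FC or expression")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def read_counts_tsv(path: str) -> pd.DataFrame:
    """Read a counts TSV whose first column is gene_id."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])


def write_counts_tsv(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")
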