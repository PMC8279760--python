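"""Translation-efficiency change (ΔTE) with jackknife Z-scores.

Translation efficiency contrasts ribosome-bound abundance (TRAP pull-down)
with total mRNA abundance.  On the log2(count+1) scale, the mutant-vs-control
change is a difference of differences over four sample groups:

    ΔTE = (TRAP_mut − TRAP_ctl) − (RNA_mut − RNA_ctl)

so a gene whose total RNA halves while its ribosome binding is unchanged
scores ΔTE = +1.  Per-gene variability is estimated by leave-one-out
resampling: ΔTE is recomputed over the Cartesian product of single-sample
deletions in the four groups (a seeded subsample of at most ``max_resamples``
combinations when the product is larger), and the spread is converted to a
standard-error estimate by the usual jackknife rescaling (see
:func:`jackknife_scale_factor`).  Z = ΔTE / sd is thresholded at |Z| > 4,
whose one-sided normal tail is ≈ 3.17e-5.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import InsufficientDataError, ValidationError
from .expression import cpm, log_transform, validate_sample_sheet

logger = logging.getLogger(__name__)

GROUP_ORDER = ("trap_mutant", "trap_control", "rna_mutant", "rna_control")
GROUP_SIGNS = {"trap_mutant": 1.0, "trap_control": -1.0, "rna_mutant": -1.0, "rna_control": 1.0}


def delta_te_from_means(
    trap_mut: float, trap_ctl: float, rna_mut: float, rna_ctl: float
) -> float:
    return (trap_mut - trap_ctl) - (rna_mut - rna_ctl)


def jackknife_scale_factor(group_sizes: Sequence[int]) -> float:
    """Rescaling from the spread of simultaneous leave-one-out values to a
    standard error of ΔTE.

    With one value deleted per group, the leave-one-out group means vary
    with variance s²_g/(n_g−1)² around the full mean, so the resampled ΔTE
    values have expected variance Σ σ²_g/(n_g(n_g−1)); the estimator's true
    variance is Σ σ²_g/n_g.  Under a common within-group variance the exact
    correction is

        c² = (Σ 1/n_g) / (Σ 1/(n_g(n_g−1)))

    which equals 1 when every group has two samples (the delete-one spread
    is then already on the right scale).
    """
    sizes = np.asarray(group_sizes, dtype=float)
    if (sizes < 2).any():
        raise InsufficientDataError("every group needs at least 2 samples")
    num = float(np.sum(1.0 / sizes))
    den = float(np.sum(1.0 / (sizes * (sizes - 1.0))))
    return float(np.sqrt(num / den))


def _loo_means(x: np.ndarray) -> np.ndarray:
    """Leave-one-out means along the last axis: shape (..., n) → (..., n)."""
    n = x.shape[-1]
    if n < 2:
        raise InsufficientDataError("leave-one-out undefined for a group of size 1")
    total = x.sum(axis=-1, keepdims=True)
    return (total - x) / (n - 1)


def jackknife_resamples(
    groups: Mapping[str, np.ndarray],
    max_resamples: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Resampled ΔTE values under simultaneous single deletions.

    ``groups`` maps each of the four group names to an array whose last axis
    is samples (1-D for one gene, 2-D genes × samples).  Returns an array of
    resampled ΔTE values with the combination axis last.  When the full
    Cartesian product exceeds ``max_resamples``, a seeded uniform subsample
    (without replacement) of combinations is used.
    """
    loo = {g: _loo_means(np.atleast_2d(groups[g]).astype(float)) for g in GROUP_ORDER}
    sizes = [loo[g].shape[-1] for g in GROUP_ORDER]
    total = int(np.prod(sizes))
    combos = np.array(list(itertools.product(*(range(n) for n in sizes))), dtype=np.intp)
    if total > max_resamples:
        rng = np.random.default_rng(seed)
        pick = rng.choice(total, size=max_resamples, replace=False)
        combos = combos[np.sort(pick)]
    vals = np.zeros((loo[GROUP_ORDER[0]].shape[0], len(combos)))
    for j, g in enumerate(GROUP_ORDER):
        vals += GROUP_SIGNS[g] * loo[g][:, combos[:, j]]
    return vals


def jackknife_sd(
    groups: Mapping[str, np.ndarray],
    max_resamples: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Jackknife standard error of ΔTE (per gene).

    Sample standard deviation of the resampled ΔTE values, rescaled by
    :func:`jackknife_scale_factor` so that it estimates the standard error
    of the ΔTE estimator rather than the raw spread of leave-one-out values.
    """
    vals = jackknife_resamples(groups, max_resamples=max_resamples, seed=seed)
    c = jackknife_scale_factor([np.atleast_2d(groups[g]).shape[-1] for g in GROUP_ORDER])
    return vals.std(axis=-1, ddof=1) * c


def te_zscore(delta: np.ndarray, sd: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Z = ΔTE / sd with the documented degenerate conventions.

    sd = 0 with ΔTE = 0 gives z = 0; sd = 0 with ΔTE ≠ 0 gives z = NaN and
    an ``unstable`` flag (returned as the second array) — a silent variance
    floor would hide such pathologies.
    """
    delta = np.asarray(delta, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if (sd < 0).any():
        raise ValidationError("negative jackknife sd")
    unstable = (sd == 0) & (delta != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, delta / np.where(sd > 0, sd, 1.0), 0.0)
    z = np.where(unstable, np.nan, z)
    return z, unstable


def z_to_p(z) -> np.ndarray:
    """One-sided upper-tail standard-normal p-value, P(N(0,1) ≥ z)."""
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise ValidationError("z must be finite")
    return stats.norm.sf(z)


@dataclass
class GroupShiftResult:
    """Welch t comparison of ΔTE between a gene set and its complement."""

    t: float
    p: float
    n_set: int
    n_rest: int
    mean_set: float
    mean_rest: float
    ecdf_set: pd.DataFrame
    ecdf_rest: pd.DataFrame


def ecdf_table(values: Iterable[float]) -> pd.DataFrame:
    """Two-column ECDF table (value, cumulative fraction)."""
    v = np.sort(np.asarray(list(values), dtype=float))
    frac = np.arange(1, len(v) + 1) / len(v)
    return pd.DataFrame({"value": v, "cumulative_fraction": frac})


def group_shift_test(
    delta_te: pd.Series, members: Iterable[str]
) -> GroupShiftResult:
    """Welch two-sample t test of ΔTE, gene set vs all other genes."""
    members = set(members)
    in_set = delta_te.index.isin(members)
    a = delta_te[in_set].dropna().to_numpy()
    b = delta_te[~in_set].dropna().to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("need at least 2 genes in the set and its complement")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return GroupShiftResult(
        float(t), float(p), len(a), len(b), float(a.mean()), float(b.mean()),
        ecdf_table(a), ecdf_table(b),
    )


class TranslationEfficiency:
    """ΔTE model over paired total-RNA and TRAP count matrices.

    Parameters
    ----------
    rna_counts, trap_counts : DataFrame, genes × samples
    sample_sheet : DataFrame with sample_id, genotype, assay (``RNA``/``TRAP``),
        animal_id; one sheet covering both matrices (or pass per-assay sheets
        concatenated)
    library_scale : counts-per-million before log2(x+1) (default True);
        switch off for exact-arithmetic checks
    """

    def __init__(
        self,
        rna_counts: pd.DataFrame,
        trap_counts: pd.DataFrame,
        sample_sheet: pd.DataFrame,
        library_scale: bool = True,
    ):
        self.sheet = validate_sample_sheet(
            sample_sheet, list(rna_counts.columns) + list(trap_counts.columns)
        )
        common = rna_counts.index.intersection(trap_counts.index)
        dropped = len(rna_counts.index.union(trap_counts.index)) - len(common)
        if dropped:
            logger.info("%d genes absent from one assay; dropped", dropped)
        self.rna = rna_counts.loc[common]
        self.trap = trap_counts.loc[common]
        self.library_scale = library_scale
        self._groups: Dict[str, List[str]] = {}
        for name, assay, genotype in (
            ("rna_control", "RNA", "control"),
            ("rna_mutant", "RNA", "mutant"),
            ("trap_control", "TRAP", "control"),
            ("trap_mutant", "TRAP", "mutant"),
        ):
            cols = self.sheet.loc[
                (self.sheet["assay"] == assay) & (self.sheet["genotype"] == genotype),
                "sample_id",
            ].tolist()
            mat = self.rna if assay == "RNA" else self.trap
            cols = [c for c in cols if c in mat.columns]
            if len(cols) < 2:
                raise InsufficientDataError(
                    f"group {name} has {len(cols)} samples; need at least 2"
                )
            self._groups[name] = cols

    @classmethod
    def from_tsv(
        cls, rna_path: str, trap_path: str, sheet_path: str, **kw
    ) -> "TranslationEfficiency":
        from .expression import read_counts_tsv

        return cls(
            read_counts_tsv(rna_path),
            read_counts_tsv(trap_path),
            pd.read_csv(sheet_path, sep="\t"),
            **kw,
        )

    def _transformed_groups(self) -> Dict[str, np.ndarray]:
        rna = cpm(self.rna) if self.library_scale else self.rna
        trap = cpm(self.trap) if self.library_scale else self.trap
        rna_l, trap_l = log_transform(rna), log_transform(trap)
        return {
            "rna_control": rna_l[self._groups["rna_control"]].to_numpy(float),
            "rna_mutant": rna_l[self._groups["rna_mutant"]].to_numpy(float),
            "trap_control": trap_l[self._groups["trap_control"]].to_numpy(float),
            "trap_mutant": trap_l[self._groups["trap_mutant"]].to_numpy(float),
        }

    def delta_te(self) -> pd.Series:
        """Point estimate of ΔTE per gene."""
        g = self._transformed_groups()
        d = (
            g["trap_mutant"].mean(axis=1)
            - g["trap_control"].mean(axis=1)
            - (g["rna_mutant"].mean(axis=1) - g["rna_control"].mean(axis=1))
        )
        return pd.Series(d, index=self.rna.index, name="delta_te")

    def fit(
        self, max_resamples: int = 100, seed: int = 0, z_threshold: float = 4.0
    ) -> "TEResults":
        g = self._transformed_groups()
        delta = self.delta_te()
        sd = jackknife_sd(g, max_resamples=max_resamples, seed=seed)
        z, unstable = te_zscore(delta.to_numpy(), sd)
        finite = np.isfinite(z)
        p_up = np.full_like(sd, np.nan)
        p_two = np.full_like(sd, np.nan)
        p_up[finite] = stats.norm.sf(z[finite])
        p_two[finite] = 2.0 * stats.norm.sf(np.abs(z[finite]))
        cls = np.where(
            finite & (z > z_threshold),
            "increased",
            np.where(finite & (z < -z_threshold), "decreased", "unchanged"),
        )
        frame = pd.DataFrame(
            {
                "delta_te": delta.to_numpy(),
                "jackknife_sd": sd,
                "z": z,
                "p_upper": p_up,
                "p_twosided": p_two,
                "unstable_flag": unstable,
                "class": cls,
            },
            index=self.rna.index,
        )
        frame.index.name = "gene_id"
        sizes = {k: len(v) for k, v in self._groups.items()}
        return TEResults(frame, z_threshold=z_threshold, group_sizes=sizes,
                         max_resamples=max_resamples, seed=seed)


@dataclass
class TEResults:
    """Per-gene ΔTE estimates, jackknife spreads, Z-scores and classes."""

    frame: pd.DataFrame
    z_threshold: float
    group_sizes: Dict[str, int]
    max_resamples: int
    seed: int

    def classify(self, z_threshold: Optional[float] = None) -> Tuple[list, list]:
        """(increased, decreased) gene lists at |Z| strictly above the threshold."""
        zt = self.z_threshold if z_threshold is None else z_threshold
        z = self.frame["z"]
        increased = self.frame.index[(z > zt)].tolist()
        decreased = self.frame.index[(z < -zt)].tolist()
        return increased, decreased

    def group_shift_test(self, members: Iterable[str]) -> GroupShiftResult:
        return group_shift_test(self.frame["delta_te"], members)

    def summary(self) -> str:
        inc, dec = self.classify()
        f = self.frame
        lines = [
            "Translation-efficiency change (jackknife ΔTE)",
            "  groups: " + ", ".join(f"{k}={v}" for k, v in self.group_sizes.items()),
            f"  genes: {len(f)}   resamples/gene: ≤{self.max_resamples}",
            f"  mean ΔTE: {f['delta_te'].mean():.4g}   median: {f['delta_te'].median():.4g}",
            f"  |Z| > {self.z_threshold:g}: {len(inc)} increased, {len(dec)} decreased",
            f"  unstable (sd = 0, ΔTE ≠ 0): {int(f['unstable_flag'].sum())}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path: str) -> None:
        self.frame.to_csv(path, sep="\t", float_format="%.17g")


def classify_te(results: TEResults, z_threshold: float = 4.0) -> Tuple[list, list]:
    """Functional alias for :meth:`TEResults.classify`."""
    return results.classify(z_threshold)
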