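"""Validation layer: cross-readout IC50 concordance, the cumulative-variance
robustness scan, and per-feature weight reports.

The package ships a reference IC50 comparison table (proliferation assay vs
spheroid area vs composite metric, four cell lines x six compounds,
published mean values) used to check the concordance statistics; censored
entries (">x", "n/a") never enter a correlation — the audit pair list
records exactly which rows were used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .dose_response import CensoredIC50

READOUTS = ("proliferative", "metric", "area")


def parse_censored(text) -> CensoredIC50:
    """Parse a printed IC50 cell: a number, '>bound', or 'n/a'."""
    s = str(text).strip().replace(",", "")
    if s.lower() in ("n/a", "na", "nan", ""):
        return CensoredIC50("not_determinable")
    if s.startswith(">"):
        return CensoredIC50("greater_than", value=float(s[1:]))
    if s.startswith("<"):
        return CensoredIC50("less_than", value=float(s[1:]))
    return CensoredIC50("definite", value=float(s))


@dataclass
class IC50Table:
    """(cell_line, compound) rows with one :class:`CensoredIC50` per readout."""

    rows: pd.DataFrame  # columns: cell_line, compound, plus CensoredIC50 columns

    def __post_init__(self) -> None:
        if self.rows.duplicated(subset=["cell_line", "compound"]).any():
            raise ValueError("duplicate (cell_line, compound) rows")

    @property
    def readouts(self) -> list[str]:
        return [c for c in self.rows.columns if c not in ("cell_line", "compound")]

    def definite_pairs(self, a: str, b: str) -> pd.DataFrame:
        """Rows where both readouts carry definite numeric IC50s."""
        sel = self.rows.apply(
            lambda r: r[a].is_definite and r[b].is_definite, axis=1
        )
        out = self.rows.loc[sel, ["cell_line", "compound"]].copy()
        out[a] = [x.value for x in self.rows.loc[sel, a]]
        out[b] = [x.value for x in self.rows.loc[sel, b]]
        return out.reset_index(drop=True)


def load_reference_table() -> IC50Table:
    """The shipped reference IC50 comparison table."""
    with resources.files("spheromet.data").joinpath("reference_ic50.csv").open() as fh:
        raw = pd.read_csv(fh)
    for col in READOUTS:
        raw[col] = raw[col].map(parse_censored)
    return IC50Table(raw)


@dataclass
class CorrelationResult:
    n_pairs: int
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    scale: str
    pairs: pd.DataFrame = field(repr=False, default=None)


def concordance(
    tbl: IC50Table, readout_a: str, readout_b: str, scale: str = "linear"
) -> CorrelationResult:
    """Pearson and Spearman concordance of two readouts' definite IC50s.

    Censored and undeterminable rows are excluded; at least 3 usable pairs
    are required.  ``scale`` is 'linear' or 'log10'.
    """
    if scale not in ("linear", "log10"):
        raise ValueError("scale must be 'linear' or 'log10'")
    pairs = tbl.definite_pairs(readout_a, readout_b)
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} usable pairs; need >= 3")
    x = pairs[readout_a].to_numpy(dtype=float)
    y = pairs[readout_b].to_numpy(dtype=float)
    if scale == "log10":
        x, y = np.log10(x), np.log10(y)
    r, pr = stats.pearsonr(x, y)
    rho, ps = stats.spearmanr(x, y)
    return CorrelationResult(
        n_pairs=len(pairs), pearson_r=float(r), pearson_p=float(pr),
        spearman_rho=float(rho), spearman_p=float(ps), scale=scale, pairs=pairs,
    )


def robustness_scan(
    feature_table,
    fluor_ic50s: dict | None = None,
    thresholds: tuple[float, ...] = (0.80, 0.90, 0.95),
) -> dict:
    """Re-run the weighting + curve-fitting stages at several
    cumulative-variance thresholds and correlate the resulting IC50s.

    Returns per-threshold IC50 tables, the pairwise Pearson/Spearman matrix
    between the threshold runs (definite IC50s on matching (cell line,
    compound) keys), and, when a proliferative IC50 mapping is supplied,
    the correlation of each run against it.  A single-threshold scan
    degenerates to one table and no cross-correlations.
    """
    from .pipeline import run_morphometric_pipeline

    thresholds = tuple(thresholds)
    if any(not 0 < t <= 1 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1]")
    tables: dict[float, pd.DataFrame] = {}
    for t in thresholds:
        res = run_morphometric_pipeline(feature_table, cum_var_threshold=t)
        tables[t] = res.ic50
    out = {"thresholds": thresholds, "ic50_tables": tables, "pairwise": {}, "vs_reference": {}}

    def definite_vector(df: pd.DataFrame) -> pd.Series:
        sel = df["ic50"].map(lambda x: x.is_definite)
        return pd.Series(
            [x.value for x in df.loc[sel, "ic50"]],
            index=pd.MultiIndex.from_frame(df.loc[sel, ["cell_line", "compound"]]),
        )

    vecs = {t: definite_vector(tables[t]) for t in thresholds}
    for i, ta in enumerate(thresholds):
        for tb in thresholds[i + 1:]:
            joined = pd.concat([vecs[ta], vecs[tb]], axis=1, join="inner").dropna()
            if len(joined) >= 3:
                r = stats.pearsonr(joined.iloc[:, 0], joined.iloc[:, 1])[0]
                rho = stats.spearmanr(joined.iloc[:, 0], joined.iloc[:, 1])[0]
            else:
                r = rho = np.nan
            out["pairwise"][(ta, tb)] = {"pearson_r": float(r), "spearman_rho": float(rho),
                                         "n": len(joined)}
    if fluor_ic50s:
        ref = pd.Series(fluor_ic50s)
        ref.index = pd.MultiIndex.from_tuples(ref.index)
        for t in thresholds:
            joined = pd.concat([vecs[t], ref], axis=1, join="inner").dropna()
            if len(joined) >= 3:
                r = stats.pearsonr(joined.iloc[:, 0], joined.iloc[:, 1])[0]
                rho = stats.spearmanr(joined.iloc[:, 0], joined.iloc[:, 1])[0]
                out["vs_reference"][t] = {"pearson_r": float(r), "spearman_rho": float(rho),
                                          "n": len(joined)}
    return out


def weight_report(weights_by_cell_line: dict) -> pd.DataFrame:
    """Tidy per-cell-line weight table with ranks and cross-line ranges.

    Rank 1 is the highest-weighted feature; ties share the average rank.
    The returned frame carries one row per (cell_line, feature) plus
    ``weight_min``/``weight_max`` columns giving that feature's range
    across cell lines.
    """
    if not weights_by_cell_line:
        raise ValueError("no weightings supplied")
    rows = []
    for cl, w in weights_by_cell_line.items():
        # round before ranking so numerically identical weights tie
        ranks = pd.Series(np.round(w.weights, 12), index=w.feature_names).rank(ascending=False)
        for name, wt in zip(w.feature_names, w.weights):
            rows.append({"cell_line": cl, "feature": name, "weight": float(wt),
                         "rank": float(ranks[name])})
    df = pd.DataFrame(rows)
    spans = df.groupby("feature")["weight"].agg(weight_min="min", weight_max="max")
    return df.merge(spans, on="feature")
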