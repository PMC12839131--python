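"""End-to-end orchestration: feature table -> QC -> normalisation ->
direction alignment -> PCA weighting -> composite metric -> 4PL IC50.

This is the morphometric arm of the screen.  The fluorescence arm
(:func:`run_fluorescence_pipeline`) applies the CV-based plate rules and
fits the same 4PL model to the cleaned viability means, so both readouts
produce comparable censored IC50s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import qc
from .dose_response import CensoredIC50, DoseSeries, FourPLFit, classify_ic50, fit_4pl
from .plate_io import FeatureTable
from .weighting import (
    NormalizedFeatureMatrix,
    PCAWeighting,
    composite_metric_per_cell_line,
    compute_weights_per_cell_line,
    conditional_invert,
    normalize_to_control,
    recheck_revert,
)


@dataclass
class PipelineResult:
    metric: pd.DataFrame  # per-well sigma with metadata
    weights: dict[str, PCAWeighting]
    matrix: NormalizedFeatureMatrix
    ic50: pd.DataFrame  # cell_line, compound, fit, ic50 (CensoredIC50)
    qc_log: list = field(default_factory=list)


def dixon_clean_table(table: FeatureTable, rel_tol: float = 0.05) -> tuple[FeatureTable, list]:
    """Dixon single-replacement applied per (cell line, compound, feature)
    across the dose-ordered triplicates of a feature table."""
    df = table.data.copy()
    log = []
    for (cl, cpd), grp in df.groupby(["cell_line", "compound"], sort=False):
        for feat in table.feature_columns:
            trips = {}
            index_of = {}
            ok = True
            for conc, sub in grp.groupby("concentration_nM"):
                sub = sub.sort_values("replicate")
                if len(sub) != 3:
                    ok = False
                    break
                trips[float(conc)] = sub[feat].to_numpy(dtype=float)
                index_of[float(conc)] = sub.index
            if not ok or len(trips) < 2:
                continue
            cleaned, decisions = qc.dixon_replace(trips, rel_tol=rel_tol)
            for conc, vals in cleaned.items():
                df.loc[index_of[conc], feat] = vals
            for d in decisions:
                if d.action != "none":
                    d.key = (cl, cpd, feat) + tuple(d.key)
                    log.append(d)
    return FeatureTable(df, provenance=table.provenance, extra=table.extra), log


def run_morphometric_pipeline(
    table: FeatureTable,
    cum_var_threshold: float = 0.90,
    apply_qc: bool = True,
    standardize: bool = True,
) -> PipelineResult:
    """Full morphometric analysis of a screen feature table."""
    qc_log: list = []
    if apply_qc:
        table, qc_log = dixon_clean_table(table)
    matrix, _ = normalize_to_control(table)
    matrix = conditional_invert(matrix)
    matrix = recheck_revert(matrix)
    weights = compute_weights_per_cell_line(
        matrix, cum_var_threshold=cum_var_threshold, standardize=standardize
    )
    metric = composite_metric_per_cell_line(matrix, weights)

    rows = []
    for (cl, cpd), grp in metric.groupby(["cell_line", "compound"], sort=False):
        treated = grp[grp["concentration_nM"] > 0]
        agg = treated.groupby("concentration_nM")["sigma"].agg(["mean", "std"])
        series = DoseSeries(
            concentrations=agg.index.to_numpy(),
            responses=agg["mean"].to_numpy(),
            sds=agg["std"].to_numpy(),
            readout="metric",
        )
        fit = fit_4pl(series)
        rows.append({"cell_line": cl, "compound": cpd, "fit": fit,
                     "ic50": classify_ic50(fit, series)})
    ic50 = pd.DataFrame(rows)
    return PipelineResult(metric=metric, weights=weights, matrix=matrix,
                         ic50=ic50, qc_log=qc_log)


def run_fluorescence_pipeline(fluor: pd.DataFrame) -> pd.DataFrame:
    """CV-rule QC plus 4PL fitting of the viability readout.

    ``fluor`` columns: cell_line, compound, concentration_nM, replicate,
    rfu.  Responses are normalised to the cleaned control mean before
    fitting.  Returns one row per (cell_line, compound) with the fit and a
    censored IC50 (``not_determinable`` on plate invalidation).
    """
    rows = []
    for (cl, cpd), grp in fluor.groupby(["cell_line", "compound"], sort=False):
        trips = {}
        for conc, sub in grp.groupby("concentration_nM"):
            vals = sub.sort_values("replicate")["rfu"].to_numpy(dtype=float)
            if len(vals) != 3:
                raise ValueError("fluorescence QC requires triplicates")
            trips[float(conc)] = vals
        cleaned, validity = qc.apply_fluorescence_rules(trips)
        if validity.status == "invalid" or 0.0 not in cleaned:
            rows.append({"cell_line": cl, "compound": cpd, "fit": None,
                         "ic50": CensoredIC50("not_determinable",
                                              reason="; ".join(validity.reasons))})
            continue
        ctrl = cleaned[0.0]
        doses = sorted(c for c in cleaned if c > 0)
        series = DoseSeries(
            concentrations=np.array(doses),
            responses=np.array([cleaned[c] / ctrl for c in doses]),
            readout="proliferative",
            qc_invalid=False,
        )
        fit = fit_4pl(series)
        rows.append({"cell_line": cl, "compound": cpd, "fit": fit,
                     "ic50": classify_ic50(fit, series)})
    return pd.DataFrame(rows)
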