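"""Pattern-level structure–property statistics and the E_rel model.

The electronic properties (HOMO, LUMO, HOMO–LUMO gap, adiabatic
ionization potential and electron affinity) follow the annelation
patterns through delta_clar; the relative energy E_rel — the energy of
an isomer above its lowest-energy constitutional isomer — additionally
feels geometric strain.  The pattern-level model fitted here is

    E_rel_avg = alpha * n_strain_avg + beta * delta_clar + gamma

with alpha > 0 (strain destabilizes) and beta < 0 (fixed-sextet
aromaticity stabilizes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .clar import pattern_delta_clar

logger = logging.getLogger(__name__)

#: Conversion constant for total energies given in hartree.
HARTREE_TO_KCALMOL = 627.5095

#: The six properties summarised per pattern (when present).
PROPERTY_COLUMNS = ("HOMO_eV", "LUMO_eV", "gap_eV", "aIP_eV", "aEA_eV",
                    "Erel_kcalmol")


class TrendsError(ValueError):
    pass


@dataclass(frozen=True)
class FitModel:
    """The pattern-level linear model for average relative energy."""

    alpha: float       # kcal/mol per n_strain unit
    beta: float        # kcal/mol per delta_clar unit
    gamma: float       # kcal/mol
    r_squared: float

    def predict(self, n_strain_avg: float, delta_clar: float) -> float:
        return self.alpha * n_strain_avg + self.beta * delta_clar + self.gamma


def predict_erel(model: FitModel, n_strain_avg: float, delta_clar: float) -> float:
    """Predicted average relative energy, kcal/mol."""
    return model.predict(n_strain_avg, delta_clar)


# ---------------------------------------------------------------------------
# relative energy


def relative_energy(records: pd.DataFrame, energy_col: str = "Etot",
                    unit_col: str = "Etot_unit") -> pd.DataFrame:
    """Add an ``Erel_kcalmol`` column: energy above the group minimum.

    Groups are ring-count (``n_rings``) cohorts — the constitutional
    isomer families.  Energies may be tagged 'hartree' or 'kcal/mol'
    per row; mixing units within a cohort is rejected.
    """
    if energy_col not in records or "n_rings" not in records:
        raise TrendsError(f"records need '{energy_col}' and 'n_rings' columns")
    df = records.copy()
    units = df[unit_col] if unit_col in df else pd.Series(
        "kcal/mol", index=df.index)
    factor = units.map({"hartree": HARTREE_TO_KCALMOL, "kcal/mol": 1.0})
    if factor.isna().any():
        bad = sorted(units[factor.isna()].unique())
        raise TrendsError(f"unknown energy unit(s): {bad}")
    kcal = df[energy_col].astype(float) * factor
    out = []
    for n_rings, idx in df.groupby("n_rings").groups.items():
        if units.loc[idx].nunique() > 1:
            raise TrendsError(f"mixed energy units in n_rings={n_rings} group")
        grp = kcal.loc[idx]
        out.append(grp - grp.min())
    df["Erel_kcalmol"] = pd.concat(out).reindex(df.index)
    return df


def check_gap_consistency(records: pd.DataFrame, tol: float = 1e-3) -> pd.DataFrame:
    """Rows where the tabulated gap disagrees with LUMO - HOMO by > tol eV."""
    needed = {"HOMO_eV", "LUMO_eV", "gap_eV"}
    if not needed <= set(records.columns):
        return records.iloc[0:0]
    resid = (records["gap_eV"] - (records["LUMO_eV"] - records["HOMO_eV"])).abs()
    bad = records[resid > tol]
    if len(bad):
        logger.warning("%d record(s) violate gap = LUMO - HOMO", len(bad))
    return bad


# ---------------------------------------------------------------------------
# pattern summaries


def pattern_summary(records: pd.DataFrame,
                    patterns: Mapping[str, str] | None = None,
                    properties: Iterable[str] | None = None,
                    n_strain_mode: str = "sample") -> pd.DataFrame:
    """Per-pattern mean and standard deviation of the properties.

    ``patterns`` maps record id to annelation pattern when the table
    has no ``pattern`` column.  Each summary row also carries the
    pattern-level ``delta_clar`` and the pattern's average strain score
    ``n_strain_avg`` — by default the mean over the pattern's
    single-annelation sample isomers (mode ``"sample"``); mode
    ``"dataset"`` averages the table's own ``n_strain`` column instead.
    """
    df = records.copy()
    if "pattern" not in df:
        if patterns is None:
            raise TrendsError("no 'pattern' column and no pattern mapping")
        df["pattern"] = df["id"].map(patterns)
    unclassified = df[df["pattern"].isna()]
    if len(unclassified):
        raise TrendsError(
            f"unclassified records: {sorted(unclassified['id'])}")
    if properties is None:
        properties = [c for c in PROPERTY_COLUMNS if c in df.columns]
    if n_strain_mode == "sample":
        strain_avg = _sample_strain_averages()
    elif n_strain_mode == "dataset":
        if "n_strain" not in df:
            raise TrendsError("'dataset' mode needs an n_strain column")
        strain_avg = df.groupby("pattern")["n_strain"].mean().to_dict()
    else:
        raise TrendsError(f"unknown n_strain_mode {n_strain_mode!r}")
    rows = []
    for pattern, grp in df.groupby("pattern", sort=True):
        row = {"pattern": pattern, "count": len(grp),
               "delta_clar": pattern_delta_clar(pattern).delta_clar,
               "n_strain_avg": strain_avg[pattern]}
        for prop in properties:
            row[f"{prop}_mean"] = grp[prop].mean()
            row[f"{prop}_sd"] = grp[prop].std(ddof=1) if len(grp) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def _sample_strain_averages() -> dict[str, float]:
    from .annelation import annelation_report
    from .strain import molecule_motifs, n_strain
    from .synthetic_data import sample_strain_set

    scores: dict[str, list[float]] = {}
    for name, b in sample_strain_set().items():
        pattern = name.rsplit("_", 1)[0]
        score = n_strain(molecule_motifs(b, annelation_report(b)))
        scores.setdefault(pattern, []).append(score)
    return {p: float(np.mean(v)) for p, v in scores.items()}


# ---------------------------------------------------------------------------
# regressions


def regress_property_vs_deltaclar(summaries: pd.DataFrame, prop: str,
                                  split: str | None = None) -> pd.DataFrame:
    """OLS of a pattern-mean property on delta_clar, optionally split.

    One output row per subgroup: slope, intercept, r_squared, n.
    Degenerate subgroups (< 3 points) are skipped with a log entry;
    a constant property gives slope 0 with undefined (NaN) R².
    """
    col = f"{prop}_mean" if f"{prop}_mean" in summaries else prop
    if col not in summaries:
        raise TrendsError(f"no column {prop!r} in summaries")
    groups = (summaries.groupby(split) if split is not None
              else [(None, summaries)])
    rows = []
    for key, grp in groups:
        if len(grp) < 3:
            logger.warning("subgroup %r skipped: only %d point(s)", key, len(grp))
            continue
        x = grp["delta_clar"].astype(float).to_numpy()
        y = grp[col].astype(float).to_numpy()
        if np.ptp(x) == 0:
            logger.warning("subgroup %r skipped: delta_clar is constant", key)
            continue
        slope, intercept = np.polyfit(x, y, 1)
        ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        if ss_tot == 0:
            slope = 0.0
        rows.append({"group": key, "slope": slope, "intercept": intercept,
                     "r_squared": r2, "n": len(grp)})
    return pd.DataFrame(rows)


def fit_erel_model(summaries: pd.DataFrame,
                   erel_col: str = "Erel_kcalmol_mean") -> FitModel:
    """Fit E_rel_avg = alpha*n_strain_avg + beta*delta_clar + gamma.

    Plain OLS on the pattern-level points (normally the 8 patterns).
    """
    if erel_col not in summaries and "Erel_kcalmol" in summaries:
        erel_col = "Erel_kcalmol"
    for col in ("n_strain_avg", "delta_clar", erel_col):
        if col not in summaries:
            raise TrendsError(f"summaries lack column {col!r}")
    if len(summaries) < 4:
        raise TrendsError("need at least 4 pattern-level points")
    x = sm.add_constant(summaries[["n_strain_avg", "delta_clar"]].astype(float))
    fit = sm.OLS(summaries[erel_col].astype(float), x).fit()
    return FitModel(alpha=float(fit.params["n_strain_avg"]),
                    beta=float(fit.params["delta_clar"]),
                    gamma=float(fit.params["const"]),
                    r_squared=float(fit.rsquared))
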