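"""End-to-end analysis driver.

Reproduces the shape of a full stratified-heterogeneity study on an accident
table: split the records into the fatal and the injuries-only group, screen
each group's outcome for spatial autocorrelation (Moran's I), run the factor
detector over every coded factor with significance masking, the risk
detector over the significant factors, the interaction detector over all
factor pairs with a type-share summary, and optionally a secondary
("combined factor") detection that ranks the joint strata of two chosen
factors by mean severity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import detectors, spatial
from .records import AccidentTable, Stratification, split_groups, stratify

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "run_analysis",
    "combined_detection",
    "interaction_type_shares",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings of one analysis run."""

    alpha: float = 0.05            # masking level for factor significance
    n_perm: int = 999
    knn_k: int = 8
    seed: int = 0
    confidence: float = 0.95       # risk-detector confidence level
    top_k: int = 10
    combined_factors: tuple[str, str] | None = None
    factors: tuple[str, ...] | None = None    # None = all coded factors


@dataclass
class FactorRow:
    factor: str
    q: float | None                # None when masked (non-significant)
    p_value: float
    masked: bool


@dataclass
class OutcomeSection:
    outcome: str
    n: int
    moran: spatial.MoranResult | None
    factor_table: list[FactorRow]
    risk_tables: dict[str, detectors.RiskComparison]
    interaction_matrix: dict[tuple[str, str], detectors.InteractionResult]
    type_shares: dict[str, float]
    combined_ranking: pd.DataFrame | None = None


@dataclass
class AnalysisReport:
    sections: dict[str, OutcomeSection]
    n_records: int
    n_excluded: int
    config: AnalysisConfig
    warnings: list[str] = field(default_factory=list)

    def factor_frame(self, outcome: str) -> pd.DataFrame:
        """Factor table as a DataFrame; masked rows show no q (mirroring a
        '-' entry in a published table)."""
        rows = self.sections[outcome].factor_table
        return pd.DataFrame(
            {
                "factor": [r.factor for r in rows],
                "q": [np.nan if r.masked else r.q for r in rows],
                "p_value": [r.p_value for r in rows],
                "masked": [r.masked for r in rows],
            }
        )

    def interaction_frame(self, outcome: str) -> pd.DataFrame:
        mat = self.sections[outcome].interaction_matrix
        return pd.DataFrame(
            [
                {"factor_a": a, "factor_b": b, "q_a": r.q_a, "q_b": r.q_b,
                 "q_ab": r.q_ab, "q_sum": r.q_sum, "type": r.type_label}
                for (a, b), r in mat.items()
            ]
        )

    def to_dict(self) -> dict:
        out = {
            "n_records": self.n_records,
            "n_excluded": self.n_excluded,
            "settings": vars(self.config).copy(),
            "warnings": list(self.warnings),
            "outcomes": {},
        }
        out["settings"]["combined_factors"] = (
            list(self.config.combined_factors)
            if self.config.combined_factors else None
        )
        out["settings"]["factors"] = (
            list(self.config.factors) if self.config.factors else None
        )
        for name, sec in self.sections.items():
            out["outcomes"][name] = {
                "n": sec.n,
                "moran": sec.moran.to_dict() if sec.moran else None,
                "factor_table": [vars(r).copy() for r in sec.factor_table],
                "risk_tables": {f: rc.to_dict() for f, rc in sec.risk_tables.items()},
                "interactions": [
                    {"pair": [a, b], **r.to_dict()}
                    for (a, b), r in sec.interaction_matrix.items()
                ],
                "type_shares": sec.type_shares,
                "combined_ranking": (
                    sec.combined_ranking.to_dict(orient="records")
                    if sec.combined_ranking is not None else None
                ),
            }
        return out

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def interaction_type_shares(
    matrix: Mapping | list,
) -> dict[str, float]:
    """Proportion of factor pairs per interaction type (sums to 1)."""
    results = list(matrix.values()) if isinstance(matrix, Mapping) else list(matrix)
    if not results:
        raise ValueError("empty interaction matrix")
    shares = {label: 0.0 for label in detectors.INTERACTION_TYPES}
    for r in results:
        shares[r.type_label] += 1.0
    total = float(len(results))
    return {k: v / total for k, v in shares.items() if v > 0 or k in shares}


def combined_detection(table: AccidentTable, factor_a: str, factor_b: str,
                       outcome: str, top_k: int = 10,
                       confidence: float = 0.95) -> pd.DataFrame:
    """Secondary detection of a combined factor.

    Overlays the two factors and ranks the joint strata by mean outcome
    (descending).  Each of the ``top_k`` leading strata is tested (Welch t,
    one-sided) for a mean significantly higher than the pooled complement.
    """
    sa = stratify(table, factor_a)
    sb = stratify(table, factor_b)
    both = detectors.overlay(sa, sb)
    y = table.outcome(outcome)[both.index]
    labels = both.labels.astype(str)
    frame = pd.DataFrame({"label": labels, "y": y})
    stats_ = frame.groupby("label")["y"].agg(["count", "mean"])
    if (stats_["count"] < 2).all():
        raise ValueError("every overlay cell has fewer than 2 records")
    stats_ = stats_.sort_values(["mean", "count"], ascending=[False, False])
    from scipy import stats as sps

    rows = []
    alpha = 1.0 - confidence
    for rank, (label, row) in enumerate(stats_.head(top_k).iterrows(), start=1):
        inside = frame.loc[frame["label"] == label, "y"].to_numpy()
        outside = frame.loc[frame["label"] != label, "y"].to_numpy()
        if len(inside) >= 2 and len(outside) >= 2 and (
            inside.std() > 0 or outside.std() > 0
        ):
            t, p_two = sps.ttest_ind(inside, outside, equal_var=False)
            p_one = p_two / 2 if t > 0 else 1 - p_two / 2
        else:
            t, p_one = np.nan, np.nan
        rows.append(
            {
                "rank": rank,
                "stratum": label,
                "n": int(row["count"]),
                "mean": float(row["mean"]),
                "t_vs_rest": float(t) if np.isfinite(t) else np.nan,
                "p_one_sided": float(p_one) if np.isfinite(p_one) else np.nan,
                "significantly_higher": bool(
                    np.isfinite(p_one) and p_one <= alpha
                ),
            }
        )
    return pd.DataFrame(rows)


def _analyse_outcome(table: AccidentTable, outcome: str,
                     config: AnalysisConfig,
                     warnings: list[str]) -> OutcomeSection:
    y = table.outcome(outcome)
    factor_names = list(config.factors) if config.factors else table.factor_names
    # spatial dependence screen
    moran = None
    try:
        w = spatial.build_weights(table.coords(), k=config.knn_k)
        moran = spatial.moran_i(y, w)
    except ValueError as exc:
        warnings.append(f"{outcome}: Moran's I unavailable ({exc})")

    strats: dict[str, Stratification] = {
        name: stratify(table, name) for name in factor_names
    }
    rows: list[FactorRow] = []
    rng = np.random.default_rng(config.seed)
    for name in factor_names:
        res = detectors.compute_q(y, strats[name])
        p = detectors.q_significance(
            y, strats[name], n_perm=config.n_perm,
            seed=int(rng.integers(2**31 - 1)),
        )
        masked = bool(p > config.alpha)
        rows.append(FactorRow(factor=name, q=None if masked else res.q,
                              p_value=p, masked=masked))

    risk_tables = {
        row.factor: detectors.risk_detector(
            y, strats[row.factor], confidence=config.confidence
        )
        for row in rows
        if not row.masked
    }

    # all unordered pairs, masked factors included: a pair of individually
    # weak factors can still combine into a strong joint stratification
    matrix: dict[tuple[str, str], detectors.InteractionResult] = {}
    for i, a in enumerate(factor_names):
        for b in factor_names[i + 1:]:
            matrix[(a, b)] = detectors.interaction_detector(
                y, strats[a], strats[b]
            )
    shares = interaction_type_shares(matrix) if matrix else {}

    combined = None
    if config.combined_factors is not None:
        fa, fb = config.combined_factors
        try:
            combined = combined_detection(
                table, fa, fb, outcome, top_k=config.top_k,
                confidence=config.confidence,
            )
        except ValueError as exc:
            warnings.append(f"{outcome}: combined detection failed ({exc})")

    return OutcomeSection(
        outcome=outcome, n=table.n, moran=moran, factor_table=rows,
        risk_tables=risk_tables, interaction_matrix=matrix,
        type_shares=shares, combined_ranking=combined,
    )


def run_analysis(table: AccidentTable,
                 config: AnalysisConfig | None = None) -> AnalysisReport:
    """Full two-group analysis of an accident table.

    Splits the records into the fatal group (analysed on fatalities) and the
    injuries-only group (analysed on injuries) and runs every detector on
    each non-empty group.
    """
    config = config or AnalysisConfig()
    warnings: list[str] = []
    g1, g2, excluded = split_groups(table)
    sections: dict[str, OutcomeSection] = {}
    for group, outcome in ((g1, "fatalities"), (g2, "injuries")):
        if group is None:
            warnings.append(f"group for outcome {outcome!r} is empty; skipped")
            continue
        sections[outcome] = _analyse_outcome(group, outcome, config, warnings)
    return AnalysisReport(
        sections=sections, n_records=table.n, n_excluded=excluded,
        config=config, warnings=warnings,
    )
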