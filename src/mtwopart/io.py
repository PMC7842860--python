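"""CSV reading, result serialization, and publication-style tables."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import Family, ModelSpec, SemicontinuousDataset
from .estimation import FitResult

__all__ = ["AnalysisConfig", "read_dataset", "write_dataset", "result_to_json", "format_table"]

logger = logging.getLogger("mtwopart")


@dataclass
class AnalysisConfig:
    """Everything a fit run needs, mappable from CLI flags or a YAML file."""

    input: str | Path = ""
    outcome: str = "y"
    cluster: str = "cluster"
    zero_covariates: tuple[str, ...] = ()
    cont_covariates: tuple[str, ...] = ()
    family: str = "LN"
    marginalized: bool = True
    quad_order: int = 15
    ci_level: float = 0.95
    seed: int = 0
    output_prefix: str = "mtp"
    verbosity: str = "info"

    def model_spec(self) -> ModelSpec:
        return ModelSpec(
            family=Family(self.family),
            marginalized=self.marginalized,
            zero_covariates=self.zero_covariates,
            cont_covariates=self.cont_covariates,
            cluster_column=self.cluster,
        )


def read_dataset(path: str | Path, config: AnalysisConfig) -> SemicontinuousDataset:
    """Read and validate a CSV into a SemicontinuousDataset.

    Rows with a missing outcome or cluster are dropped (with a logged
    count); a negative outcome is a hard error naming the offending row;
    a non-numeric outcome is reported per row.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    needed = [config.outcome, config.cluster, *config.zero_covariates, *config.cont_covariates]
    for col in needed:
        if col not in df.columns:
            raise KeyError(f"column {col!r} missing from {path}")
    y_raw = pd.to_numeric(df[config.outcome], errors="coerce")
    bad = df[config.outcome].notna() & y_raw.isna()
    if bad.any():
        rows = ", ".join(str(i) for i in df.index[bad][:10])
        raise ValueError(f"non-numeric outcome values at rows: {rows}")
    keep = y_raw.notna() & df[config.cluster].notna()
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d rows with missing outcome or cluster", dropped)
    df = df.loc[keep].copy()
    df[config.outcome] = y_raw.loc[keep]
    neg = df.index[df[config.outcome] < 0]
    if len(neg):
        raise ValueError(f"negative outcome at row {neg[0]}: y={df.loc[neg[0], config.outcome]}")
    return SemicontinuousDataset.from_dataframe(
        df, config.outcome, config.cluster, config.zero_covariates, config.cont_covariates
    )


def write_dataset(data: SemicontinuousDataset, path: str | Path,
                  outcome: str = "y", cluster: str = "cluster") -> None:
    data.to_dataframe(outcome, cluster).to_csv(path, index=False)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, Family):
        return obj.value
    if isinstance(obj, pd.DataFrame):
        return [_jsonify(rec) for rec in obj.to_dict(orient="records")]
    if dataclasses.is_dataclass(obj):
        return {k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def result_to_json(result: FitResult) -> str:
    """Machine-readable fit result; floats keep full precision (repr)."""
    payload = {
        "family": result.spec.family.value,
        "marginalized": result.spec.marginalized,
        "names": result.names,
        "estimates": _jsonify(result.estimates),
        "se": _jsonify(result.se),
        "vcov": _jsonify(result.vcov),
        "loglik": result.loglik,
        "converged": result.converged,
        "n_obs": result.n_obs,
        "n_clusters": result.n_clusters,
        "effect_table": _jsonify(result.effect_table),
        "diagnostics": _jsonify(result.diagnostics),
    }
    return json.dumps(payload, indent=2, allow_nan=True)


def format_table(result: FitResult) -> str:
    """Human-readable coefficient table in the two-part journal layout.

    Zero and nonzero components side by side with the random-intercept
    variances; significant effects (p < .05) are starred; transforms are
    blank when the fit did not converge (the dash convention).
    """
    p = result.params
    lines = []
    fam = result.spec.family.value
    kind = "marginalized two-part" if result.spec.marginalized else "conventional two-part"
    lines.append(f"{kind} model ({fam}), n={result.n_obs}, clusters={result.n_clusters}")
    lines.append(f"log-likelihood: {result.loglik:.4f}   converged: {result.converged}")
    lines.append(f"var(b1): {p.sd_b1**2:.4f}   var(b2): {p.sd_b2**2:.4f}   "
                 f"dispersion: {p.dispersion:.4f}")
    lines.append("")
    header = (f"{'part':<5} {'covariate':<16} {'coef':>9} {'se':>8} "
              f"{'transform':>14} {'value':>8} {'95% CI':>19}  sig")
    lines.append(header)
    lines.append("-" * len(header))
    for _, row in result.effect_table.iterrows():
        if result.converged:
            lo, hi = row["value_ci_low"], row["value_ci_high"]
            if row["part"] == "zero" and row["estimate"] < 0:
                # reciprocal scale, endpoints conventionally printed descending
                tname, tval = "zero-odds fold", f"{row['alt_value']:.2f}"
                ci = f"({1 / lo:.2f}, {1 / hi:.2f})"
            elif row["part"] == "zero":
                tname, tval = "odds ratio", f"{row['value']:.2f}"
                ci = f"({lo:.2f}, {hi:.2f})"
            elif row["estimate"] < 0:
                tname, tval = "% reduction", f"{row['alt_value']:.2f}"
                ci = f"({100 * (1 - hi):.2f}, {100 * (1 - lo):.2f})"
            else:
                tname, tval = "mean ratio", f"{row['value']:.2f}"
                ci = f"({lo:.2f}, {hi:.2f})"
        else:
            tname, tval, ci = "—", "—", "—"  # nonconverged: leave cells empty
        star = "*" if row["significant"] and result.converged else ""
        lines.append(
            f"{row['part']:<5} {row['name']:<16} {row['estimate']:>9.4f} "
            f"{row['se']:>8.4f} {tname:>14} {tval:>8} {ci:>19}  {star}"
        )
    return "\n".join(lines)
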