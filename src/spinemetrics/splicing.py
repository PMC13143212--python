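"""Relative-expression and exon-inclusion arithmetic.

The downstream quantification layer for qRT-PCR and junction-level
splicing data: 2^−ΔCq relative expression against a reference gene,
inclusion fraction of an alternative exon from splice-specific vs
wild-type-specific assays, averaging of splice-border PSI (percent spliced
in) values into an exon inclusion probability, and per-group summaries.
Upstream alignment / junction discovery is out of scope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def rel_expression(cq_target, cq_reference):
    """Relative expression 2^−(Cq_target − Cq_reference)."""
    cq_t = np.asarray(cq_target, dtype=float)
    cq_r = np.asarray(cq_reference, dtype=float)
    if not (np.all(np.isfinite(cq_t)) and np.all(np.isfinite(cq_r))):
        raise ValueError("Cq values must be finite")
    out = 2.0 ** (-(cq_t - cq_r))
    return out if out.ndim else float(out)


def fraction_inclusion(expr_variant: float, expr_wildtype: float) -> float:
    """Exon inclusion fraction: variant / (variant + wild type), both as
    relative expressions of the splice-specific and wild-type-specific
    assays."""
    if expr_variant < 0 or expr_wildtype < 0:
        raise ValueError("expressions must be non-negative")
    total = expr_variant + expr_wildtype
    if total == 0:
        raise ValueError("both expressions are zero: fraction undefined")
    return expr_variant / total


def aggregate_psi(junction_psis) -> float:
    """Exon inclusion probability: arithmetic mean of the exon's
    splice-border PSI values."""
    psis = np.asarray(list(junction_psis), dtype=float)
    if psis.size == 0:
        raise ValueError("no junction PSI values supplied")
    if np.any((psis < 0) | (psis > 1)):
        raise ValueError("PSI values must lie in [0, 1]")
    return float(psis.mean())


def cq_table_expression(table: pd.DataFrame) -> pd.DataFrame:
    """Add a ``rel_expr`` (2^−ΔCq) column to a Cq table with columns
    sample_id, target_gene, reference_gene, Cq_target, Cq_reference
    (template_volume, if present, is carried through as metadata)."""
    required = {"sample_id", "target_gene", "reference_gene",
                "Cq_target", "Cq_reference"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Cq table missing columns {sorted(missing)}")
    out = table.copy()
    out["rel_expr"] = rel_expression(out["Cq_target"].to_numpy(),
                                     out["Cq_reference"].to_numpy())
    return out


def psi_table_inclusion(table: pd.DataFrame) -> pd.DataFrame:
    """Average junction PSIs per sample into one exon inclusion
    probability; expects columns sample_id, junction_id, psi."""
    required = {"sample_id", "junction_id", "psi"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"PSI table missing columns {sorted(missing)}")
    rows = [
        {"sample_id": sid, "exon_inclusion": aggregate_psi(sub["psi"])}
        for sid, sub in table.groupby("sample_id", sort=True)
    ]
    return pd.DataFrame(rows)


def group_summary(values: pd.Series | np.ndarray, groups) -> pd.DataFrame:
    """Per-group mean, s.d. (n−1 denominator), s.e.m. and n."""
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "group": list(groups)})
    rows = []
    for g, sub in df.groupby("group", sort=True):
        v = sub["value"].to_numpy()
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        rows.append({"group": g, "n": v.size, "mean": float(v.mean()),
                     "sd": sd, "sem": sd / np.sqrt(v.size)})
    return pd.DataFrame(rows)
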