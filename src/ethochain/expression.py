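"""qPCR relative expression (2^−ΔΔCt) and qPCR-vs-RNA-seq sign concordance.

The Livak 2^−ΔΔCt method: per sample, ΔCt = Ct(target) − Ct(reference
gene); ΔΔCt = mean ΔCt(treated group) − mean ΔCt(control group); relative
expression (fold change) = 2^−ΔΔCt.  Per-replicate fold changes are each
treated sample's ΔCt referenced to the control-group mean, so their
geometric mean equals the summary fold change exactly.  Primer-efficiency
correction (Pfaffl) is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CtRecord",
    "FoldChangeComparison",
    "FoldChangeResult",
    "ddct_fold_change",
    "sign_concordance",
]


@dataclass(frozen=True)
class CtRecord:
    """One qPCR cycle-threshold measurement."""

    sample_id: str
    group: str
    gene: str
    ct: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.ct):
            raise ValueError(f"Ct for {self.sample_id}/{self.gene} is not finite")


@dataclass(frozen=True)
class FoldChangeComparison:
    """log2 fold changes of one gene from the two platforms."""

    gene: str
    log2fc_qpcr: float
    log2fc_rnaseq: float


@dataclass(frozen=True)
class FoldChangeResult:
    """2^−ΔΔCt output: per-replicate fold changes plus the summary."""

    gene: str
    ddct: float
    fold_change: float          # 2^−ΔΔCt == geometric mean of per_replicate
    log2_fold_change: float
    per_replicate: pd.Series    # treated sample → fold change vs control mean


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            [
                {"sample_id": r.sample_id, "group": r.group, "gene": r.gene, "ct": r.ct}
                for r in records
            ]
        )
    required = {"sample_id", "group", "gene", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing column(s): {sorted(missing)}")
    dup = df.duplicated(subset=["sample_id", "gene"])
    if dup.any():
        pairs = df.loc[dup, ["sample_id", "gene"]].to_records(index=False).tolist()
        raise ValueError(f"duplicate (sample, gene) Ct entries: {pairs}")
    if not np.isfinite(df["ct"].astype(float)).all():
        raise ValueError("all Ct values must be finite")
    return df


def ddct_fold_change(
    records,
    target_gene: str,
    ref_gene: str,
    treated_group: str,
    control_group: str,
) -> FoldChangeResult:
    """Relative expression of ``target_gene`` in treated vs control group.

    ``records`` is a list of :class:`CtRecord` or a DataFrame with columns
    ``sample_id, group, gene, ct``.  Every sample contributing a target Ct
    must also have a Ct for the reference gene (e.g. 18S rRNA).
    """
    df = _records_frame(records)
    target = df[df["gene"] == target_gene].set_index("sample_id")
    ref = df[df["gene"] == ref_gene].set_index("sample_id")
    if target.empty:
        raise ValueError(f"no Ct values for target gene {target_gene!r}")
    no_ref = sorted(set(target.index) - set(ref.index))
    if no_ref:
        raise ValueError(f"samples missing reference gene {ref_gene!r}: {no_ref}")
    dct = target["ct"].astype(float) - ref.loc[target.index, "ct"].astype(float)
    groups = target["group"]
    dct_treated = dct[groups == treated_group]
    dct_control = dct[groups == control_group]
    for name, series in ((treated_group, dct_treated), (control_group, dct_control)):
        if series.empty:
            raise ValueError(f"group {name!r} has no samples for {target_gene!r}")
    ddct = float(dct_treated.mean() - dct_control.mean())
    per_replicate = np.exp2(-(dct_treated - dct_control.mean())).rename("fold_change")
    return FoldChangeResult(
        gene=target_gene,
        ddct=ddct,
        fold_change=float(2.0 ** (-ddct)),
        log2_fold_change=float(-ddct),
        per_replicate=per_replicate,
    )


def sign_concordance(comparisons) -> float:
    """Fraction of genes whose qPCR and RNA-seq log2 fold changes agree in
    sign (zero agrees only with zero).

    ``comparisons`` is a nonempty list of :class:`FoldChangeComparison`
    (or (gene, log2fc_qpcr, log2fc_rnaseq) tuples) or a DataFrame with
    columns ``log2fc_qpcr`` and ``log2fc_rnaseq``.
    """
    if isinstance(comparisons, pd.DataFrame):
        if comparisons.empty:
            raise ValueError("comparison table is empty")
        q = comparisons["log2fc_qpcr"].astype(float).to_numpy()
        r = comparisons["log2fc_rnaseq"].astype(float).to_numpy()
    else:
        rows = list(comparisons)
        if not rows:
            raise ValueError("comparison list is empty")
        if isinstance(rows[0], FoldChangeComparison):
            q = np.array([c.log2fc_qpcr for c in rows], dtype=float)
            r = np.array([c.log2fc_rnaseq for c in rows], dtype=float)
        else:
            q = np.array([c[1] for c in rows], dtype=float)
            r = np.array([c[2] for c in rows], dtype=float)
    if not (np.isfinite(q).all() and np.isfinite(r).all()):
        raise ValueError("log2 fold changes must be finite")
    return float(np.mean(np.sign(q) == np.sign(r)))
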