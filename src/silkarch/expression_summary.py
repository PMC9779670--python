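"""Replicate- and gland-aware TPM aggregation and proportional expression.

Silk-gland RNA-seq designs replicate each tissue two or three times and, for
some glands, sequence anatomical subregions separately.  Aggregation averages
subregions into their parent gland first, then replicates (arithmetic mean).
Proportional expression is the ratio of a gene's tissue TPM to its summed TPM
across tissues, with a scaled variant multiplying the proportion by the
log-transformed summed TPM (log2(x + 1) by default).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import ValidationError

__all__ = [
    "TpmMatrix",
    "ProportionTable",
    "read_tpm_tsv",
    "aggregate_replicates",
    "proportional_expression",
    "group_summary",
]

META_COLUMNS = ("sample_id", "tissue", "replicate", "subregion")


class TpmMatrix:
    """Genes x samples TPM values plus sample metadata.

    ``values``: DataFrame indexed by gene_id with sample_id columns.
    ``metadata``: DataFrame with columns sample_id, tissue, replicate,
    subregion (subregion empty string when the tissue was not subdivided).
    """

    def __init__(self, values: pd.DataFrame, metadata: pd.DataFrame):
        if (values.values < 0).any():
            raise ValidationError("negative TPM value")
        missing = [c for c in META_COLUMNS if c not in metadata.columns]
        if missing:
            raise ValidationError(f"metadata missing columns {missing}")
        unknown = set(values.columns) - set(metadata["sample_id"])
        if unknown:
            raise ValidationError(f"samples without metadata: {sorted(unknown)}")
        if metadata["tissue"].isna().any() or (metadata["tissue"] == "").any():
            raise ValidationError("every sample needs a tissue label")
        self.values = values.astype(float)
        self.metadata = metadata.reset_index(drop=True)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return sorted(self.metadata["tissue"].unique())


class ProportionTable:
    """Genes x tissues proportional expression.

    ``proportions`` rows sum to 1 for genes with non-zero total TPM;
    ``scaled`` multiplies each proportion by the log-transformed summed TPM.
    ``undefined`` flags all-zero genes whose proportions are meaningless.
    """

    def __init__(self, proportions: pd.DataFrame, scaled: pd.DataFrame,
                 undefined: pd.Series):
        self.proportions = proportions
        self.scaled = scaled
        self.undefined = undefined


def read_tpm_tsv(values_path: str | Path, metadata_path: str | Path) -> TpmMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    metadata = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
    return TpmMatrix(values, metadata)


def aggregate_replicates(m: TpmMatrix) -> pd.DataFrame:
    """Collapse samples to one column per tissue.

    Subregion samples are averaged into their parent (tissue, replicate)
    first, then replicates are averaged — a two-stage arithmetic mean, not a
    TPM re-normalization.
    """
    meta = m.metadata[m.metadata["sample_id"].isin(m.values.columns)]
    out: dict[str, pd.Series] = {}
    for tissue, tmeta in meta.groupby("tissue", sort=True):
        rep_means = []
        for _, rmeta in tmeta.groupby("replicate"):
            rep_means.append(m.values[list(rmeta["sample_id"])].mean(axis=1))
        if not rep_means:
            continue
        out[tissue] = pd.concat(rep_means, axis=1).mean(axis=1)
    return pd.DataFrame(out, index=m.values.index)


def proportional_expression(
    aggregated: pd.DataFrame, log_base: float = 2.0, pseudo: float = 1.0
) -> ProportionTable:
    """Per-gene tissue proportions and the log-scaled variant.

    p(g,t) = TPM(g,t) / sum_t TPM(g,t) computed on untransformed TPM;
    scaled(g,t) = p(g,t) * log_base(sum_t TPM(g,t) + pseudo).  All-zero genes
    are flagged undefined (proportions NaN).
    """
    if (aggregated.values < 0).any():
        raise ValidationError("negative TPM value")
    totals = aggregated.sum(axis=1)
    undefined = totals == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        props = aggregated.div(totals, axis=0)
    props[undefined] = np.nan
    log_totals = np.log(totals + pseudo) / np.log(log_base)
    scaled = props.mul(log_totals, axis=0)
    return ProportionTable(props, scaled, undefined)


def group_summary(
    aggregated: pd.DataFrame,
    groups: dict[str, str],
    log_base: float = 2.0,
    pseudo: float = 1.0,
) -> ProportionTable:
    """Group-level proportions: member-gene TPM is summed per group *before*
    the proportional transform.  Genes absent from ``groups`` are ignored;
    empty groups are absent from the output."""
    rows = {}
    labels = sorted(set(groups.values()))
    for label in labels:
        members = [g for g, lab in groups.items() if lab == label
                   and g in aggregated.index]
        if not members:
            continue
        rows[label] = aggregated.loc[members].sum(axis=0)
    summed = pd.DataFrame(rows).T
    summed.index.name = aggregated.index.name
    return proportional_expression(summed, log_base, pseudo)
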