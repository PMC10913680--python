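"""Upload-time pre-filtering of omics blocks.

Two pipelines, dispatched by block type:

* continuous blocks over the 10,000-feature cap: low-count removal (column
  sum < 10) then removal of the lowest-MAD columns until exactly the cap
  remains;
* microbiome count blocks (ASV/OTU tables): low-proportion feature removal
  (total count <= 0.01% of the grand total), +1 offset, total-sum scaling
  and the centered log-ratio transform. Output rows sum to zero.

Every step emits a :class:`FilterReport` so removed features stay auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import OmicsDataset, ValidationError

FEATURE_CAP = 10_000
LOW_COUNT_MIN_TOTAL = 10
MIXMC_REL_THRESHOLD = 1e-4  # 0.01 % of the grand total


@dataclass
class FilterReport:
    """Record of one filtering stage: what was removed and under which rule."""

    stage: str  # low_count | mad_cap | mixmc_low_count | clr
    removed_feature_ids: list
    parameters: dict
    n_before: int
    n_after: int

    def __post_init__(self) -> None:
        assert self.n_after == self.n_before - len(self.removed_feature_ids)
        assert self.n_after >= 0

    def to_dict(self) -> dict:
        return {"stage": self.stage, "removed_feature_ids": list(self.removed_feature_ids),
                "parameters": dict(self.parameters),
                "n_before": self.n_before, "n_after": self.n_after}


def column_mad(column) -> float:
    """Median absolute deviation, without the 1.4826 consistency constant.

    The constant is omitted deliberately: columns are only *ranked* by MAD,
    and a positive scale factor cannot change the ranking.
    """
    x = np.asarray(column, dtype=float)
    if x.size == 0:
        raise ValidationError("MAD of an empty column")
    return float(np.median(np.abs(x - np.median(x))))


def low_count_filter(ds: OmicsDataset, min_total: float = LOW_COUNT_MIN_TOTAL
                     ) -> tuple[OmicsDataset, FilterReport]:
    """Drop every feature whose column sum is strictly below `min_total`."""
    sums = ds.values.sum(axis=0)
    removed = list(ds.values.columns[sums.to_numpy() < min_total])
    report = FilterReport(stage="low_count", removed_feature_ids=removed,
                          parameters={"min_total": min_total},
                          n_before=ds.n_features,
                          n_after=ds.n_features - len(removed))
    if report.n_after == 0:
        raise ValidationError(
            f"low-count filter removed every feature of {ds.name!r}")
    kept = [c for c in ds.feature_ids if c not in set(removed)]
    out = ds.with_values(ds.values[kept], operation="low_count_filter",
                         min_total=min_total, removed=len(removed))
    return out, report


def mad_cap_filter(ds: OmicsDataset, cap: int = FEATURE_CAP,
                   min_total: float = LOW_COUNT_MIN_TOTAL
                   ) -> tuple[OmicsDataset, list[FilterReport]]:
    """Cap the feature count at `cap` by dropping the lowest-MAD columns.

    Identity below the cap. Above it, the low-count filter runs first; if
    the block is still too wide, exactly the surplus columns with the
    smallest MAD are removed (ties at the cutoff keep earlier columns).
    """
    reports: list[FilterReport] = []
    if ds.n_features <= cap:
        return ds, reports
    ds, rep = low_count_filter(ds, min_total=min_total)
    reports.append(rep)
    if ds.n_features > cap:
        mat = ds.matrix()
        feats = ds.feature_ids
        mads = np.median(np.abs(mat - np.median(mat, axis=0)), axis=0)
        # stable sort: among equal MADs, later columns are dropped first
        order = np.argsort(mads, kind="stable")
        drop_idx = set(order[: ds.n_features - cap].tolist())
        removed = [feats[j] for j in sorted(drop_idx)]
        reports.append(FilterReport(stage="mad_cap", removed_feature_ids=removed,
                                    parameters={"cap": cap},
                                    n_before=ds.n_features, n_after=cap))
        kept = [f for j, f in enumerate(feats) if j not in drop_idx]
        ds = ds.with_values(ds.values[kept], operation="mad_cap_filter",
                            cap=cap, removed=len(removed))
    return ds, reports


def mixmc_preprocess(ds: OmicsDataset, offset: float = 1.0,
                     rel_threshold: float = MIXMC_REL_THRESHOLD,
                     strict: bool = False
                     ) -> tuple[OmicsDataset, list[FilterReport]]:
    """Compositional preprocessing of a raw microbiome count block.

    1. remove features whose total raw count is <= ``rel_threshold`` x grand
       total (the 0.01 % rule; ``strict=True`` switches the comparison to <);
    2. add `offset` to every remaining cell;
    3. total-sum-scale each sample and apply the centered log-ratio:
       clr(x)_i = ln(x_i) - mean_j ln(x_j). Rows of the output sum to zero.

    The low-count rule is applied to raw totals *before* the offset. TSS
    before CLR is recorded for transparency although CLR output is invariant
    to any per-sample rescaling.
    """
    if not ds.is_microbiome:
        raise ValidationError(f"{ds.name!r} is not flagged as a microbiome block")
    mat = ds.matrix()
    if (mat < 0).any():
        raise ValidationError(f"negative counts in microbiome block {ds.name!r}")
    if not np.allclose(mat, np.round(mat)):
        raise ValidationError(f"non-integer counts in microbiome block {ds.name!r}")
    totals = mat.sum(axis=0)
    grand = totals.sum()
    cut = rel_threshold * grand
    low = totals < cut if strict else totals <= cut
    feats = ds.feature_ids
    removed = list(ds.values.columns[low])
    reports = [FilterReport(stage="mixmc_low_count", removed_feature_ids=removed,
                            parameters={"rel_threshold": rel_threshold,
                                        "strict": strict, "grand_total": float(grand)},
                            n_before=ds.n_features,
                            n_after=ds.n_features - len(removed))]
    if reports[0].n_after == 0:
        raise ValidationError(
            f"mixMC low-count rule removed every feature of {ds.name!r}")
    kept_idx = np.flatnonzero(~low)
    kept = [feats[j] for j in kept_idx]
    counts = mat[:, kept_idx] + offset
    if (counts <= 0).any():
        raise ValidationError(
            f"zero counts remain in {ds.name!r} with offset={offset}; "
            "CLR needs strictly positive values")
    tss = counts / counts.sum(axis=1, keepdims=True)
    log = np.log(tss)
    clr = log - log.mean(axis=1, keepdims=True)
    reports.append(FilterReport(stage="clr", removed_feature_ids=[],
                                parameters={"offset": offset, "tss": True},
                                n_before=len(kept), n_after=len(kept)))
    values = pd.DataFrame(clr, index=ds.values.index, columns=kept)
    out = ds.with_values(values, operation="mixmc_preprocess", offset=offset,
                         rel_threshold=rel_threshold, strict=strict,
                         removed=len(removed))
    return out, reports


def prefilter(ds: OmicsDataset, cap: int = FEATURE_CAP,
              offset: float = 1.0, rel_threshold: float = MIXMC_REL_THRESHOLD,
              strict: bool = False) -> tuple[OmicsDataset, list[FilterReport]]:
    """Dispatch upload-time filtering by block type.

    Microbiome blocks go through :func:`mixmc_preprocess`; everything else
    through :func:`mad_cap_filter`, which is the identity at or below the cap.
    """
    if ds.is_microbiome:
        return mixmc_preprocess(ds, offset=offset, rel_threshold=rel_threshold,
                                strict=strict)
    return mad_cap_filter(ds, cap=cap)
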