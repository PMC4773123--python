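"""Relative miRNA expression from qRT-PCR Ct values (2^-ddCt method).

For each (sample, assay) the cycle threshold is averaged over replicates
(typically triplicates), normalized within the sample against an endogenous
control assay (dCt = mean Ct(assay) - mean Ct(control)), referenced to a
calibrator sample (ddCt = dCt(sample) - dCt(calibrator)) and expressed as a
fold change 2^-ddCt; the calibrator's fold is 1 by construction.  Replicate
standard deviations are carried through for reporting only — no error
propagation into fold confidence intervals, and no amplification-efficiency
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, IncompleteDesignError


@dataclass
class CtMeasurement:
    """Replicate Ct values for one (sample, assay) pair."""

    sample: str
    assay: str
    replicates: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ConfigError("at least one Ct replicate is required")
        if any(not np.isfinite(ct) or ct <= 0 for ct in self.replicates):
            raise ConfigError("Ct values must be finite and positive")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.replicates))

    @property
    def sd_ct(self) -> float:
        return float(np.std(self.replicates, ddof=1)) if len(self.replicates) > 1 else 0.0


def load_ct_table(path) -> list[CtMeasurement]:
    """Load a Ct TSV: ``sample``, ``assay``, then either a single ``ct``
    column (one row per replicate) or ``ct1..ctN`` replicate columns."""
    df = pd.read_csv(path, sep="\t")
    if "ct" in df.columns:
        grouped = df.groupby(["sample", "assay"], sort=False)["ct"].apply(list)
        return [CtMeasurement(s, a, list(v)) for (s, a), v in grouped.items()]
    ct_cols = [c for c in df.columns if c.startswith("ct")]
    if not ct_cols:
        raise ConfigError("no Ct columns found (expected 'ct' or 'ct1..ctN')")
    out = []
    for row in df.itertuples():
        values = [getattr(row, c) for c in ct_cols]
        values = [float(v) for v in values if pd.notna(v)]
        out.append(CtMeasurement(row.sample, row.assay, values))
    return out


def ddct(measurements: list[CtMeasurement], reference_assay: str,
         calibrator_sample: str) -> pd.DataFrame:
    """Fold changes by the 2^-ddCt method.

    Every sample must include the reference assay and the calibrator sample
    must be present; violations raise :class:`IncompleteDesignError` naming
    the offending sample.  Returns one row per (sample, assay) with mean Ct,
    replicate SD, dCt, ddCt and fold.
    """
    by_sample: dict[str, dict[str, CtMeasurement]] = {}
    for m in measurements:
        by_sample.setdefault(m.sample, {})[m.assay] = m
    if calibrator_sample not in by_sample:
        raise IncompleteDesignError(
            f"calibrator sample {calibrator_sample!r} not present")
    for sample, assays in by_sample.items():
        if reference_assay not in assays:
            raise IncompleteDesignError(
                f"sample {sample!r} is missing the reference assay "
                f"{reference_assay!r}")

    dct = {
        (sample, assay): m.mean_ct - assays[reference_assay].mean_ct
        for sample, assays in by_sample.items()
        for assay, m in assays.items()
    }
    calibrator_dct = {
        assay: dct[(calibrator_sample, assay)]
        for assay in by_sample[calibrator_sample]
    }
    rows = []
    for sample, assays in by_sample.items():
        for assay, m in assays.items():
            delta = dct[(sample, assay)]
            if assay in calibrator_dct:
                ddelta = delta - calibrator_dct[assay]
                fold = 2.0 ** (-ddelta)
            else:  # assay absent from the calibrator: fold undefined
                ddelta, fold = np.nan, np.nan
            rows.append({
                "sample": sample,
                "assay": assay,
                "mean_ct": m.mean_ct,
                "sd_ct": m.sd_ct,
                "delta_ct": delta,
                "delta_delta_ct": ddelta,
                "fold": fold,
            })
    return pd.DataFrame(rows)


def normalize_to_assay(folds: pd.DataFrame, anchor_assay: str) -> pd.DataFrame:
    """Rescale fold changes so the anchor assay maps to 1 within each sample.

    Useful when expression is reported relative to one miRNA rather than to
    a calibrator sample.  Rescaling is idempotent; an anchor fold of 0
    raises :class:`ConfigError`.
    """
    out = folds.copy()
    for sample, group in folds.groupby("sample"):
        anchor = group.loc[group["assay"] == anchor_assay, "fold"]
        if anchor.empty:
            raise ConfigError(
                f"anchor assay {anchor_assay!r} absent from sample {sample!r}")
        value = float(anchor.iloc[0])
        if value == 0:
            raise ConfigError(f"anchor fold is 0 in sample {sample!r}; rescale undefined")
        out.loc[out["sample"] == sample, "fold"] = (
            out.loc[out["sample"] == sample, "fold"] / value)
    return out
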