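"""Relative quantitation of glycoforms and glycosylation-trait summaries.

Precursor feature intensities (one value per glycopeptide observation, from
upstream feature detection) are converted to relative abundances: within each
(sample, injection, peptide) the intensity of each accepted glycoform is
divided by the summed intensity of all accepted glycoforms sharing that
peptide, giving percentages that sum to 100 per injection. Per-sample values
are the mean over the injections in which the peptide was detected.

The per-sample table is then rolled up into the classical IgG-Fc readouts:
percent agalactosylated (G0), percent galactosylated-asialo (G1/G2), percent
sialylated (GS1+GS2), and percent fucosylated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .glycospace import label_glycoform, parse_composition

logger = logging.getLogger(__name__)

__all__ = [
    "PrecursorFeature",
    "GlycoformQuantTable",
    "features_frame",
    "select_dominant_peptide",
    "relative_quant",
    "summarize_traits",
]

_KEY = ["sample_id", "peptide", "composition"]


@dataclass(frozen=True)
class PrecursorFeature:
    """One quantified glycopeptide observation."""

    sample_id: str
    injection_id: int
    peptide: str
    composition: str
    intensity: float

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


def features_frame(features: Iterable[PrecursorFeature] | pd.DataFrame) -> pd.DataFrame:
    """Normalise feature input (records or DataFrame) to a canonical frame."""
    if isinstance(features, pd.DataFrame):
        df = features.copy()
    else:
        records = [vars(f) for f in features]
        columns = ["sample_id", "injection_id", "peptide", "composition", "intensity"]
        df = pd.DataFrame(records, columns=None if records else columns)
    required = {"sample_id", "injection_id", "peptide", "composition", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"feature table lacks columns {sorted(missing)}")
    if (df["intensity"] < 0).any():
        raise ValueError("negative feature intensity")
    return df


def select_dominant_peptide(features) -> str:
    """The glycopeptide backbone with the greatest total intensity.

    Quantitation is reported per IgG subtype; the dominant subtype is the one
    whose tryptic glycopeptide accumulates the most signal across the sample
    set (ties broken alphabetically for determinism).
    """
    df = features_frame(features)
    totals = df.groupby("peptide")["intensity"].sum().sort_values(
        ascending=False, kind="stable"
    )
    top = totals[totals == totals.iloc[0]]
    return sorted(top.index)[0]


@dataclass(frozen=True)
class GlycoformQuantTable:
    """Per-injection percentages and their per-sample means.

    ``per_injection``: sample_id, injection_id, peptide, composition, pct.
    ``per_sample``: sample_id, peptide, composition, pct_mean, n_injections.
    """

    per_injection: pd.DataFrame
    per_sample: pd.DataFrame


def relative_quant(
    features,
    accepted: Sequence[tuple[str, str, str]] | None = None,
    peptide: str | None = None,
    missing_policy: str = "zero",
) -> GlycoformQuantTable:
    """Normalise accepted glycoform intensities to percent-of-peptide.

    Parameters
    ----------
    features : PrecursorFeature records or an equivalent DataFrame. Multiple
        features of one glycoform in one injection (e.g. charge states) are
        summed before normalisation.
    accepted : optional whitelist of (sample_id, peptide, composition) keys,
        normally the verified glycoforms; unlisted rows are discarded before
        the denominator is formed. None keeps everything.
    peptide : optionally restrict to one peptide backbone; by default the
        dominant peptide (greatest total intensity) is selected.
    missing_policy : "zero" scores a glycoform absent from an injection as 0%
        whenever the peptide itself was detected there (the identified set
        defines the denominator per injection); "available" averages each
        glycoform only over the injections where it was observed.
    """
    if missing_policy not in ("zero", "available"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    df = features_frame(features)
    if accepted is not None:
        keys = set(accepted)
        df = df[
            [tuple(k) in keys for k in df[_KEY].itertuples(index=False, name=None)]
        ]
    if peptide is None and not df.empty:
        peptide = select_dominant_peptide(df)
    if peptide is not None:
        df = df[df["peptide"] == peptide]
    if df.empty:
        empty_inj = pd.DataFrame(
            columns=["sample_id", "injection_id", "peptide", "composition", "pct"]
        )
        empty_smp = pd.DataFrame(columns=_KEY + ["pct_mean", "n_injections"])
        return GlycoformQuantTable(empty_inj, empty_smp)

    agg = (
        df.groupby(["sample_id", "injection_id", "peptide", "composition"], sort=True)[
            "intensity"
        ]
        .sum()
        .reset_index()
    )
    totals = agg.groupby(["sample_id", "injection_id", "peptide"])["intensity"].transform(
        "sum"
    )
    zero_total = totals == 0
    if zero_total.any():
        bad = agg.loc[zero_total, ["sample_id", "injection_id", "peptide"]].drop_duplicates()
        for row in bad.itertuples(index=False):
            logger.warning(
                "zero total intensity for %s injection %s peptide %s; "
                "injection excluded from the mean",
                row.sample_id,
                row.injection_id,
                row.peptide,
            )
        agg = agg[~zero_total]
        totals = totals[~zero_total]
    agg = agg.assign(pct=100.0 * agg["intensity"] / totals).drop(columns="intensity")

    if missing_policy == "zero":
        # complete the glycoform grid: 0% where the peptide was seen but the
        # glycoform was not
        filled = []
        for (sample, pep), sub in agg.groupby(["sample_id", "peptide"], sort=True):
            grid = pd.MultiIndex.from_product(
                [sorted(sub["injection_id"].unique()), sorted(sub["composition"].unique())],
                names=["injection_id", "composition"],
            )
            wide = (
                sub.set_index(["injection_id", "composition"])["pct"]
                .reindex(grid, fill_value=0.0)
                .reset_index()
            )
            wide.insert(0, "sample_id", sample)
            wide.insert(2, "peptide", pep)
            filled.append(wide)
        per_injection = pd.concat(filled, ignore_index=True)
    else:
        per_injection = agg[
            ["sample_id", "injection_id", "peptide", "composition", "pct"]
        ].reset_index(drop=True)

    per_sample = (
        per_injection.groupby(_KEY, sort=True)["pct"]
        .agg(pct_mean="mean", n_injections="size")
        .reset_index()
    )
    return GlycoformQuantTable(per_injection, per_sample)


def summarize_traits(table: GlycoformQuantTable) -> pd.DataFrame:
    """Per-sample glycosylation-trait summary.

    Columns: ``G0_pct`` (agalactosylated, any fucosylation/bisection),
    ``G1G2_pct`` (galactosylated, asialo), ``GS_pct`` (all sialylated,
    GS1+GS2), ``other_pct`` (non-biantennary forms) — these four partition
    100% — plus ``fuc_pct`` (fucosylated forms, overlapping the others).
    """
    df = table.per_sample.copy()
    if df.empty:
        return pd.DataFrame(
            columns=["sample_id", "G0_pct", "G1G2_pct", "GS_pct", "other_pct", "fuc_pct"]
        ).set_index("sample_id")
    labels = {c: label_glycoform(parse_composition(c)) for c in df["composition"].unique()}

    def trait(comp: str) -> str:
        lab = labels[comp]
        if lab.galactose_state == "other":
            return "other_pct"
        if lab.sialo_state > 0:
            return "GS_pct"
        return "G0_pct" if lab.galactose_state == "G0" else "G1G2_pct"

    df["trait"] = df["composition"].map(trait)
    out = (
        df.pivot_table(
            index="sample_id", columns="trait", values="pct_mean", aggfunc="sum"
        )
        .reindex(columns=["G0_pct", "G1G2_pct", "GS_pct", "other_pct"], fill_value=0.0)
        .fillna(0.0)
    )
    out["fuc_pct"] = (
        df[df["composition"].map(lambda c: labels[c].fucosylated)]
        .groupby("sample_id")["pct_mean"]
        .sum()
        .reindex(out.index, fill_value=0.0)
    )
    out.columns.name = None
    return out
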