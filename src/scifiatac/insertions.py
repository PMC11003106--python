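"""Tn5 insertion sites, per-nucleus QC metrics and nuclei calling.

Aligned fragments are converted to single-base Tn5 integration sites by
shifting the fragment start by +4 and the end by -5 (the two transposase
insertion points of the 9-bp staggered cut), deduplicated per cell, and
summarised into the four QC metrics used to call high-quality nuclei:
unique-site count, fraction of sites within 2 kb of a TSS, fraction inside
accessible chromatin regions (FRiP), and fraction on organelle scaffolds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TSS_WINDOW = 2000  # bp, symmetric, endpoints inclusive


@dataclass
class QCThresholds:
    """Inclusive per-nucleus pass thresholds ("a minimum of" semantics)."""

    min_sites: int = 1000
    min_frac_tss: float = 0.20
    min_frip: float = 0.20
    max_frac_organelle: float = 0.30

    def __post_init__(self) -> None:
        for v in (self.min_frac_tss, self.min_frip, self.max_frac_organelle):
            if not 0.0 <= v <= 1.0:
                raise ValueError("fraction thresholds must lie in [0, 1]")


def fragment_to_insertions(
    start: int, end: int, chrom_length: int | None = None
) -> tuple[int, int, bool, bool]:
    """Convert one 0-based half-open fragment to its two Tn5 sites.

    Returns (plus_site, minus_site, degenerate, clipped): plus-side site at
    start+4, minus-side site at end-5. Fragments shorter than 10 bp yield
    crossed sites and are flagged degenerate; sites outside the chromosome
    are clipped into range and flagged.
    """
    if not 0 <= start < end:
        raise ValueError("need 0 <= start < end")
    plus, minus = start + 4, end - 5
    degenerate = minus <= plus  # fragment < 10 bp: the two sites cross or coincide
    clipped = False
    if chrom_length is not None:
        hi = chrom_length - 1
        for p in (plus, minus):
            if p < 0 or p > hi:
                clipped = True
        plus = min(max(plus, 0), hi)
        minus = min(max(minus, 0), hi)
    return plus, minus, degenerate, clipped


def insertions_from_fragments(
    fragments: pd.DataFrame,
    barcode_col: str = "barcode",
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Vectorised +4/-5 conversion of a fragment table to insertion sites.

    Emits two rows per fragment (columns: chrom, pos, barcode, degenerate);
    extra columns of the input are carried through. Sites beyond chromosome
    ends are clipped when ``chrom_lengths`` is given.
    """
    start = fragments["start"].to_numpy()
    end = fragments["end"].to_numpy()
    plus = start + 4
    minus = end - 5
    degenerate = minus <= plus
    carry = [
        c for c in fragments.columns if c not in ("start", "end")
    ]
    half = fragments[carry].reset_index(drop=True)
    sites = pd.concat([half, half], ignore_index=True)
    sites["pos"] = np.concatenate([plus, minus])
    sites["degenerate"] = np.concatenate([degenerate, degenerate])
    if chrom_lengths is not None:
        lens = sites["chrom"].map(chrom_lengths).to_numpy()
        sites["pos"] = np.clip(sites["pos"], 0, lens - 1)
    if barcode_col != "barcode" and barcode_col in sites:
        sites = sites.rename(columns={barcode_col: "barcode"})
    return sites


def dedupe_insertions(sites: pd.DataFrame) -> pd.DataFrame:
    """Keep one record per (barcode, chrom, pos); idempotent."""
    return sites.drop_duplicates(
        subset=["barcode", "chrom", "pos"], ignore_index=True
    )


def dedupe_report(sites: pd.DataFrame) -> pd.DataFrame:
    """Per-cell site counts before and after deduplication."""
    before = sites.groupby("barcode", observed=True).size().rename("n_sites")
    after = (
        dedupe_insertions(sites)
        .groupby("barcode", observed=True)
        .size()
        .rename("n_unique_sites")
    )
    return pd.concat([before, after], axis=1).fillna(0).astype(int).reset_index()


# -- interval membership ----------------------------------------------------

def merge_intervals(intervals: pd.DataFrame) -> dict[str, np.ndarray]:
    """Merge possibly-overlapping half-open intervals per chromosome.

    Returns chrom -> flat sorted boundary array [s0, e0, s1, e1, ...]; a
    position p is inside iff searchsorted(bounds, p, 'right') is odd.
    """
    out: dict[str, np.ndarray] = {}
    for chrom, grp in intervals.groupby("chrom", observed=True):
        iv = grp[["start", "end"]].to_numpy()
        iv = iv[np.argsort(iv[:, 0])]
        merged = []
        for s, e in iv:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[str(chrom)] = np.asarray(merged, dtype=np.int64).ravel()
    return out


def in_intervals(
    chroms: np.ndarray, pos: np.ndarray, merged: dict[str, np.ndarray]
) -> np.ndarray:
    """Membership of single-base positions in merged half-open intervals."""
    hit = np.zeros(len(pos), dtype=bool)
    ser = pd.Series(np.arange(len(pos)))
    for chrom, idx in ser.groupby(pd.Series(chroms).astype(str).to_numpy()):
        bounds = merged.get(chrom)
        if bounds is None or len(bounds) == 0:
            continue
        ii = idx.to_numpy()
        hit[ii] = np.searchsorted(bounds, pos[ii], side="right") % 2 == 1
    return hit


def tss_windows(tss: pd.DataFrame, window: int = TSS_WINDOW) -> pd.DataFrame:
    """±window intervals around TSSs, endpoints inclusive (half-open form)."""
    if tss.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.DataFrame(
        {
            "chrom": tss["chrom"].to_numpy(),
            "start": np.maximum(tss["pos"].to_numpy() - window, 0),
            "end": tss["pos"].to_numpy() + window + 1,
        }
    )


def compute_qc(
    sites: pd.DataFrame,
    tss: pd.DataFrame,
    acrs: pd.DataFrame,
    organelle_scaffolds=(),
    tss_window: int = TSS_WINDOW,
) -> pd.DataFrame:
    """Per-barcode QC metrics over unique insertion sites.

    All fractions use the full unique-site count of the cell (organelle
    sites included) as denominator. ``sites`` must already be deduplicated;
    ``tss`` has columns (chrom, pos), ``acrs`` (chrom, start, end).
    """
    if sites.empty:
        return pd.DataFrame(
            columns=[
                "barcode", "n_unique_sites", "frac_tss", "frip", "frac_organelle",
            ]
        )
    chroms = sites["chrom"].astype(str).to_numpy()
    pos = sites["pos"].to_numpy()
    in_tss = in_intervals(chroms, pos, merge_intervals(tss_windows(tss, tss_window)))
    in_acr = in_intervals(chroms, pos, merge_intervals(acrs))
    on_org = np.isin(chroms, np.asarray(list(organelle_scaffolds), dtype=str))
    agg = pd.DataFrame(
        {
            "barcode": sites["barcode"].to_numpy(),
            "n": 1,
            "tss": in_tss.astype(np.int64),
            "acr": in_acr.astype(np.int64),
            "org": on_org.astype(np.int64),
        }
    ).groupby("barcode", observed=True, sort=False).sum()
    qc = pd.DataFrame(
        {
            "barcode": agg.index.to_numpy(),
            "n_unique_sites": agg["n"].to_numpy(),
            "frac_tss": agg["tss"].to_numpy() / agg["n"].to_numpy(),
            "frip": agg["acr"].to_numpy() / agg["n"].to_numpy(),
            "frac_organelle": agg["org"].to_numpy() / agg["n"].to_numpy(),
        }
    )
    return qc.reset_index(drop=True)


def call_nuclei(
    qc: pd.DataFrame, thresholds: QCThresholds | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the four inclusive thresholds; returns (qc with 'pass', summary)."""
    t = thresholds or QCThresholds()
    out = qc.copy()
    out["pass"] = (
        (out["n_unique_sites"] >= t.min_sites)
        & (out["frac_tss"] >= t.min_frac_tss)
        & (out["frip"] >= t.min_frip)
        & (out["frac_organelle"] <= t.max_frac_organelle)
    )
    summary = {
        "n_barcodes": int(len(out)),
        "n_pass": int(out["pass"].sum()),
        "fail_sites": int((out["n_unique_sites"] < t.min_sites).sum()),
        "fail_tss": int((out["frac_tss"] < t.min_frac_tss).sum()),
        "fail_frip": int((out["frip"] < t.min_frip).sum()),
        "fail_organelle": int((out["frac_organelle"] > t.max_frac_organelle).sum()),
    }
    return out, summary
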