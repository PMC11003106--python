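"""Pseudobulk chromatin-accessibility scoring.

Gene accessibility counts Tn5 insertion sites in the gene body plus a
500-bp upstream and 100-bp downstream flank (strand-relative), per group
(cell type, genotype, or library). Raw counts are CPM-normalised per group
and converted to per-feature Z-scores across groups; features with Z above
a threshold in a group are called specific to it (ctACRs / gtACRs at
Z > 2). ACR master lists are built from 500-bp summit-centred windows with
greedy overlap resolution and a minimum-CPM filter, and libraries are
compared by Spearman correlation of their pseudobulk profiles.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

UPSTREAM_FLANK = 500
DOWNSTREAM_FLANK = 100
ACR_WINDOW = 500
MIN_CPM = 3.0
Z_SPECIFIC = 2.0


def _count_sites_in_windows(
    sites: pd.DataFrame, windows: pd.DataFrame, group_col: str = "group"
) -> pd.DataFrame:
    """Count sites per (possibly overlapping) window per group.

    Windows are half-open [start, end); counting uses sorted positions and
    searchsorted, so overlapping windows each receive their own count.
    """
    groups = sorted(sites[group_col].unique()) if len(sites) else []
    out = np.zeros((len(windows), len(groups)), dtype=np.int64)
    win_chrom = windows["chrom"].astype(str).to_numpy()
    for gi, g in enumerate(groups):
        sub = sites[sites[group_col] == g]
        for chrom, grp in sub.groupby(sub["chrom"].astype(str).to_numpy()):
            pos = np.sort(grp["pos"].to_numpy())
            wm = win_chrom == chrom
            if not wm.any():
                continue
            lo = np.searchsorted(pos, windows.loc[wm, "start"].to_numpy())
            hi = np.searchsorted(pos, windows.loc[wm, "end"].to_numpy())
            out[wm, gi] = hi - lo
    return pd.DataFrame(out, index=windows.index, columns=groups)


def gene_accessibility(
    sites: pd.DataFrame,
    genes: pd.DataFrame,
    group_col: str = "group",
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Raw gene-accessibility count matrix (genes x groups).

    Per gene the counting window is the gene body extended by 500 bp
    upstream and 100 bp downstream of transcription: [start-500, end+100)
    on +, [start-100, end+500) on -. Unstranded genes are treated as +
    with a warning.
    """
    g = genes.copy().reset_index(drop=True)
    if "strand" not in g.columns:
        warnings.warn("genes lack strand; treating all as '+'", stacklevel=2)
        g["strand"] = "+"
    unknown = ~g["strand"].isin(["+", "-"])
    if unknown.any():
        warnings.warn(
            f"{int(unknown.sum())} unstranded genes treated as '+'", stacklevel=2
        )
        g.loc[unknown, "strand"] = "+"
    plus = g["strand"].to_numpy() == "+"
    start = np.where(
        plus, g["start"] - UPSTREAM_FLANK, g["start"] - DOWNSTREAM_FLANK
    )
    end = np.where(plus, g["end"] + DOWNSTREAM_FLANK, g["end"] + UPSTREAM_FLANK)
    start = np.maximum(start, 0)
    if chrom_lengths is not None:
        lens = g["chrom"].map(chrom_lengths).to_numpy()
        end = np.minimum(end, lens)
    windows = pd.DataFrame(
        {"chrom": g["chrom"].to_numpy(), "start": start, "end": end}
    )
    counts = _count_sites_in_windows(sites, windows, group_col)
    counts.index = g.index
    return counts


def cpm(raw: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per column; zero-total columns dropped with warning."""
    totals = raw.sum(axis=0)
    dead = totals == 0
    if dead.any():
        warnings.warn(
            f"dropping zero-count groups: {list(raw.columns[dead])}", stacklevel=2
        )
    kept = raw.loc[:, ~dead]
    return kept / kept.sum(axis=0) * 1e6


def cpm_zscore(raw: pd.DataFrame) -> pd.DataFrame:
    """CPM-normalise then Z-score each feature across groups.

    Uses the sample standard deviation (ddof=1); zero-variance features get
    Z = 0 everywhere.
    """
    c = cpm(raw)
    if c.shape[1] < 2:
        raise ValueError("need >= 2 groups with nonzero counts")
    mu = c.mean(axis=1)
    sd = c.std(axis=1, ddof=1)
    z = c.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)


def build_acr_master_list(
    acrs: pd.DataFrame,
    chrom_lengths: dict[str, int] | None = None,
    window: int = ACR_WINDOW,
) -> pd.DataFrame:
    """Summit-centred fixed-width windows with greedy overlap resolution.

    ``acrs`` carries chrom, summit (or start/end, from which the midpoint is
    used with a flag) and a per-ACR signal ``count`` used to rank windows.
    Windows are laid down in descending count order; any window overlapping
    an already-accepted one is dropped, so the master list is pairwise
    non-overlapping. Windows are clipped at chromosome edges (flagged).
    """
    df = acrs.copy().reset_index(drop=True)
    if "summit" not in df.columns or df["summit"].isna().any():
        warnings.warn(
            "missing summits; using interval midpoints", stacklevel=2
        )
        mid = ((df["start"] + df["end"]) // 2).astype(np.int64)
        if "summit" not in df.columns:
            df["summit"] = mid
        else:
            df["summit"] = df["summit"].fillna(pd.Series(mid)).astype(np.int64)
        df["midpoint_summit"] = True
    if "count" not in df.columns:
        df["count"] = 1.0
    half = window // 2
    start = df["summit"].to_numpy(dtype=np.int64) - half
    end = start + window
    clipped = start < 0
    start = np.maximum(start, 0)
    if chrom_lengths is not None:
        lens = df["chrom"].map(chrom_lengths).to_numpy()
        clipped |= end > lens
        end = np.minimum(end, lens)
        start = np.minimum(start, np.maximum(end - window, 0))
    df["start"], df["end"], df["clipped"] = start, end, clipped

    keep_rows = []
    accepted: dict[str, list[tuple[int, int]]] = {}
    order = df.sort_values("count", ascending=False, kind="mergesort").index
    for i in order:
        c, s, e = str(df.at[i, "chrom"]), int(df.at[i, "start"]), int(df.at[i, "end"])
        if any(s < ae and astart < e for astart, ae in accepted.get(c, [])):
            continue
        accepted.setdefault(c, []).append((s, e))
        keep_rows.append(i)
    cols = ["chrom", "start", "end", "summit", "count", "clipped"]
    if "group" in df.columns:
        cols.append("group")
    return (
        df.loc[sorted(keep_rows), cols]
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )


def acr_accessibility(
    sites: pd.DataFrame, windows: pd.DataFrame, group_col: str = "group"
) -> pd.DataFrame:
    """Raw site counts per master-list window per group."""
    return _count_sites_in_windows(sites, windows, group_col)


def filter_by_cpm(
    windows: pd.DataFrame, raw_counts: pd.DataFrame, min_cpm: float = MIN_CPM
) -> pd.DataFrame:
    """Drop windows whose CPM is below ``min_cpm`` in every group."""
    c = cpm(raw_counts)
    keep = (c >= min_cpm).any(axis=1)
    return windows.loc[keep.to_numpy()].reset_index(drop=True)


def specific_features(
    z: pd.DataFrame, z_threshold: float = Z_SPECIFIC
) -> tuple[dict[str, list], pd.DataFrame]:
    """Features specific to each group (Z strictly above the threshold).

    Returns (group -> feature list, per-group summary with counts and the
    fraction of all features called specific there). A feature may be
    specific to more than one group.
    """
    sets = {
        g: list(z.index[z[g] > z_threshold]) for g in z.columns
    }
    summary = pd.DataFrame(
        {
            "group": list(sets),
            "n_specific": [len(v) for v in sets.values()],
            "fraction": [len(v) / len(z) if len(z) else 0.0 for v in sets.values()],
        }
    )
    return sets, summary


def library_correlation(matrix: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation between group columns (average ranks on ties).

    Constant columns have undefined rank correlation and are reported NaN.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 columns")
    rho = stats.spearmanr(matrix.to_numpy(), axis=0).statistic
    if matrix.shape[1] == 2:  # scipy returns a scalar for two columns
        rho = np.array([[1.0, rho], [rho, 1.0]])
    out = pd.DataFrame(rho, index=matrix.columns, columns=matrix.columns)
    const = matrix.nunique(axis=0) <= 1
    if const.any():
        warnings.warn(
            f"constant columns have undefined correlation: "
            f"{list(matrix.columns[const])}",
            stacklevel=2,
        )
        out.loc[const, :] = np.nan
        out.loc[:, const] = np.nan
    out.values[np.arange(len(out)), np.arange(len(out))] = 1.0
    return out
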