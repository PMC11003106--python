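"""Combined cell-barcode demultiplexing for pre-indexed droplet scATAC-seq.

A cell's identity is the pair (bead barcode, Tn5 well): the 16-bp gel-bead
barcode identifies the droplet, and the two inline 5-nt Tn5 barcodes (one on
each transposase adapter, the "A"/s7 row side and "B"/s5 column side)
identify the pre-indexing well of the 96-well plate. 12 A-barcodes crossed
with 8 B-barcodes give the 96 well combinations. This module corrects
observed barcodes against their whitelists, maps Tn5 barcode pairs to wells,
and separates genuine co-encapsulated nuclei from index-hopped background at
the (bead, well) level.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Tn5 mosaic-end sequence that follows the inline well barcode on each mate.
MOSAIC_END = "AGATGTGTATAAGAGACAG"

# Synthetic default whitelists (the two-sided 5-nt Tn5 barcode sets).
# Generated once with pairwise Hamming distance >= 3 within and across the
# two lists, so single-mismatch correction can never be ambiguous.
DEFAULT_A_BARCODES = (
    "TCGCT", "CTCGC", "TCCGA", "TTTGT", "GTGTT", "TGGGG",
    "ACACC", "CGTTC", "ATAGG", "TACAC", "AGGAT", "GTAAC",
)
DEFAULT_B_BARCODES = (
    "TTCTG", "ATCAA", "CGACT", "ACTAG", "TGTAA", "GCTTA", "TTACA", "CGCAG",
)

REJECT_REASONS = ("bad_bead", "bad_a", "bad_b", "invalid_pair")

_BASE_TO_INT = {ord(b): i for i, b in enumerate("ACGTN")}


def _encode(seqs) -> np.ndarray:
    """Encode equal-length sequences as a (n, L) uint8 matrix."""
    seqs = list(seqs)
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    out = arr.reshape(len(seqs), -1).copy()
    for byte, code in _BASE_TO_INT.items():
        out[arr.reshape(len(seqs), -1) == byte] = code
    return out


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))


def _min_pairwise_distance(seqs) -> int:
    return min(
        (hamming(a, b) for a, b in itertools.combinations(seqs, 2)),
        default=len(seqs[0]) if seqs else 0,
    )


@dataclass
class BarcodeSchema:
    """Whitelists and correction radius for the three barcode components."""

    a_barcodes: tuple[str, ...] = DEFAULT_A_BARCODES
    b_barcodes: tuple[str, ...] = DEFAULT_B_BARCODES
    bead_whitelist: tuple[str, ...] = ()
    max_mismatch: int = 1

    def __post_init__(self) -> None:
        for name, wl in (("A", self.a_barcodes), ("B", self.b_barcodes)):
            if len(set(wl)) != len(wl):
                raise ValueError(f"duplicate {name}-barcodes in whitelist")
        if len(set(self.bead_whitelist)) != len(self.bead_whitelist):
            raise ValueError("duplicate bead barcodes in whitelist")
        for name, wl in (
            ("A", self.a_barcodes),
            ("B", self.b_barcodes),
            ("bead", self.bead_whitelist),
        ):
            if len(wl) > 1 and _min_pairwise_distance(wl) <= 2 * self.max_mismatch:
                warnings.warn(
                    f"{name} whitelist has pairwise Hamming distance "
                    f"<= {2 * self.max_mismatch}; some errors may be "
                    "uncorrectable (rejected as ambiguous)",
                    stacklevel=2,
                )


@dataclass
class WellMap:
    """Bijection (A-barcode, B-barcode) -> well id, plus optional sample labels."""

    wells: dict[tuple[str, str], int]
    well_samples: dict[int, str] | None = None

    @property
    def n_wells(self) -> int:
        return len(self.wells)

    def sample_of(self, well_id: int) -> str:
        if self.well_samples is None or well_id not in self.well_samples:
            raise KeyError(f"well {well_id} has no sample label")
        return self.well_samples[well_id]


@dataclass(frozen=True)
class CellBarcode:
    bead_barcode: str
    well_id: int

    @property
    def combined(self) -> str:
        return f"{self.bead_barcode}-{self.well_id}"


def build_well_map(
    a_barcodes=DEFAULT_A_BARCODES,
    b_barcodes=DEFAULT_B_BARCODES,
    well_samples: dict[int, str] | None = None,
) -> WellMap:
    """Enumerate the full A x B cross product as wells 1..|A|*|B|.

    Wells are numbered in A-major order (all B-barcodes of the first
    A-barcode first), mirroring a plate read column by column.
    """
    for name, wl in (("A", a_barcodes), ("B", b_barcodes)):
        if not wl:
            raise ValueError(f"{name}-barcode list is empty")
        if len(set(wl)) != len(wl):
            raise ValueError(f"duplicate barcode in {name} list")
    wells = {
        (a, b): ia * len(b_barcodes) + ib + 1
        for ia, a in enumerate(a_barcodes)
        for ib, b in enumerate(b_barcodes)
    }
    return WellMap(wells=wells, well_samples=well_samples)


def correct_barcode(observed: str, whitelist, max_mismatch: int = 1) -> str | None:
    """Correct one barcode against a whitelist; None if uncorrectable.

    Returns the unique whitelist entry within Hamming distance
    ``max_mismatch``; ties at the minimum distance are rejected
    (conservative: a mis-corrected well barcode later masquerades as index
    hopping).
    """
    whitelist = list(whitelist)
    if not whitelist:
        return None
    if len(observed) != len(whitelist[0]):
        raise ValueError(
            f"observed barcode length {len(observed)} != whitelist length "
            f"{len(whitelist[0])}"
        )
    dists = [hamming(observed, w) for w in whitelist]
    best = min(dists)
    if best > max_mismatch or dists.count(best) > 1:
        return None
    return whitelist[dists.index(best)]


def correct_barcodes(
    observed: np.ndarray | list, whitelist, max_mismatch: int = 1
) -> np.ndarray:
    """Vectorised correction: returns whitelist indices, -1 where rejected."""
    observed = np.asarray(observed, dtype=object)
    wl = list(whitelist)
    if len(observed) == 0:
        return np.empty(0, dtype=np.int64)
    if len(observed[0]) != len(wl[0]):
        raise ValueError("observed barcode length != whitelist length")
    # exact matches first (the vast majority of reads), then a chunked
    # Hamming scan of the remainder against the whole whitelist
    lookup = {s: i for i, s in enumerate(wl)}
    out = np.array([lookup.get(s, -1) for s in observed], dtype=np.int64)
    miss = np.flatnonzero(out < 0)
    if len(miss) == 0 or max_mismatch == 0:
        return out
    enc_obs = _encode(observed[miss])
    enc_wl = _encode(wl)
    chunk = max(1, int(2e7) // max(1, len(wl)))
    for lo in range(0, len(miss), chunk):
        d = (enc_obs[lo : lo + chunk, None, :] != enc_wl[None, :, :]).sum(axis=2)
        best = d.min(axis=1)
        idx = d.argmin(axis=1)
        ambiguous = (d == best[:, None]).sum(axis=1) > 1
        idx[(best > max_mismatch) | ambiguous] = -1
        out[miss[lo : lo + chunk]] = idx
    return out


def parse_read_name(name: str) -> tuple[str, str]:
    """Split a read name into (read id, bead barcode).

    The 16-bp bead barcode is carried after the final underscore of the read
    name, the convention produced by UMI-tools barcode extraction.
    """
    if "_" not in name:
        raise ValueError(f"read name {name!r} carries no bead barcode suffix")
    rid, bead = name.rsplit("_", 1)
    return rid, bead


def demux_read(
    name: str,
    r1_seq: str,
    r2_seq: str,
    schema: BarcodeSchema,
    well_map: WellMap,
) -> tuple[CellBarcode, str, str] | str:
    """Demultiplex one read pair; returns (CellBarcode, trimmed R1, trimmed R2)
    on success, or a rejection reason from REJECT_REASONS."""
    _, bead_obs = parse_read_name(name)
    bead = correct_barcode(bead_obs, schema.bead_whitelist, schema.max_mismatch)
    if bead is None:
        return "bad_bead"
    bc_len = len(schema.a_barcodes[0])
    a = correct_barcode(r1_seq[:bc_len], schema.a_barcodes, schema.max_mismatch)
    if a is None:
        return "bad_a"
    b = correct_barcode(r2_seq[:bc_len], schema.b_barcodes, schema.max_mismatch)
    if b is None:
        return "bad_b"
    if (a, b) not in well_map.wells:
        return "invalid_pair"
    trim = bc_len + len(MOSAIC_END)
    return CellBarcode(bead, well_map.wells[(a, b)]), r1_seq[trim:], r2_seq[trim:]


def demux_reads(
    reads: pd.DataFrame, schema: BarcodeSchema, well_map: WellMap
) -> pd.DataFrame:
    """Vectorised demux of a read table.

    ``reads`` needs columns ``read_id``, ``bead_obs``, ``a_obs``, ``b_obs``
    (observed barcode sequences). Returns a copy with ``bead`` (corrected
    sequence), ``well`` and ``status`` ('ok' or a rejection reason).
    """
    out = reads.copy()
    n = len(out)
    bead_idx = correct_barcodes(
        out["bead_obs"].to_numpy(), schema.bead_whitelist, schema.max_mismatch
    )
    a_idx = correct_barcodes(
        out["a_obs"].to_numpy(), schema.a_barcodes, schema.max_mismatch
    )
    b_idx = correct_barcodes(
        out["b_obs"].to_numpy(), schema.b_barcodes, schema.max_mismatch
    )
    status = np.full(n, "ok", dtype=object)
    status[b_idx < 0] = "bad_b"
    status[a_idx < 0] = "bad_a"
    status[bead_idx < 0] = "bad_bead"

    a_arr = np.asarray(schema.a_barcodes, dtype=object)
    b_arr = np.asarray(schema.b_barcodes, dtype=object)
    bead_arr = np.asarray(schema.bead_whitelist, dtype=object)
    ok = status == "ok"
    well = np.full(n, -1, dtype=np.int64)
    if ok.any():
        pair_to_well = well_map.wells
        wells = np.array(
            [
                pair_to_well.get((a, b), -1)
                for a, b in zip(a_arr[a_idx[ok]], b_arr[b_idx[ok]])
            ],
            dtype=np.int64,
        )
        well[ok] = wells
        bad_pair = ok.copy()
        bad_pair[ok] = wells < 0
        status[bad_pair] = "invalid_pair"
    out["bead"] = np.where(bead_idx >= 0, bead_arr[np.maximum(bead_idx, 0)], None)
    out["well"] = well
    out["status"] = status
    out.loc[out["status"] != "ok", "bead"] = None
    out.loc[out["status"] != "ok", "well"] = -1
    return out


def count_bead_well(demuxed: pd.DataFrame) -> pd.DataFrame:
    """Tally reads per (bead, well) over successfully demuxed reads."""
    ok = demuxed[demuxed["status"] == "ok"] if "status" in demuxed else demuxed
    counts = (
        ok.groupby(["bead", "well"], observed=True)
        .size()
        .rename("reads")
        .reset_index()
    )
    return counts


def filter_bead_well_combos(
    counts: pd.DataFrame, min_reads: int = 100, min_frac: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Separate candidate nuclei from index-hopped background.

    A (bead, well) combination is retained as a candidate nucleus iff its
    read count is >= ``min_reads`` AND >= ``min_frac`` of all reads carrying
    that bead barcode. Everything else is trace signal — reads that hopped
    onto this bead barcode from another droplet — and is excluded from
    nucleus-level accounting.

    Returns (retained, flagged) DataFrames, each with columns
    ``bead``, ``well``, ``reads``, ``bead_total``, ``frac``.
    """
    if not 0.0 <= min_frac <= 1.0:
        raise ValueError("min_frac must lie in [0, 1]")
    if (counts["reads"] < 0).any():
        raise ValueError("negative read counts")
    df = counts.copy()
    df["bead_total"] = df.groupby("bead", observed=True)["reads"].transform("sum")
    df["frac"] = np.where(df["bead_total"] > 0, df["reads"] / df["bead_total"], 0.0)
    keep = (df["reads"] >= min_reads) & (df["frac"] >= min_frac)
    return df[keep].reset_index(drop=True), df[~keep].reset_index(drop=True)
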