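"""Bulk segregant analysis on SNP-array intensity tables.

Consumes per-SNP probe-intensity tables (one row per SNP x strand, with
reference- and alternate-allele intensities) from two bulk
hybridizations, restricts to SNPs known to be polymorphic between the
cross parents, forms the per-SNP difference of allele differences
between bulks, loess-smooths each chromosome, and calls candidate
regions where the smoothed trace exceeds a detection threshold
established by matched simulations.

File dialects
-------------
Intensity TSV: tab-separated with header
``snp_id  chrom  pos  strand  ref_intensity  alt_intensity``;
``strand`` is ``sense`` or ``antisense``; ``pos`` is 1-based bp.
Marker list TSV: header ``snp_id``, one SNP per line.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .array_signal import SignalBank, make_synthetic_bank
from .bsa_engine import ChromosomeTrace, SmoothedTrace, loess_smooth
from .xam_simulator import ScenarioConfig, ThresholdSet

__all__ = [
    "INTENSITY_COLUMNS",
    "IntensityTable",
    "RegionCall",
    "read_intensity_table",
    "write_intensity_table",
    "read_marker_list",
    "write_marker_list",
    "allele_difference",
    "bsa_trace",
    "call_region",
    "subsample_markers",
    "generate_fixture",
    "DEFAULT_CHROM_LENGTHS_BP",
]

logger = logging.getLogger(__name__)

INTENSITY_COLUMNS = ["snp_id", "chrom", "pos", "strand", "ref_intensity", "alt_intensity"]

#: Arabidopsis-like physical chromosome lengths (bp) for fixture generation.
DEFAULT_CHROM_LENGTHS_BP: dict[str, int] = {
    "1": 30_400_000,
    "2": 19_700_000,
    "3": 23_500_000,
    "4": 18_600_000,
    "5": 26_900_000,
}


@dataclass(frozen=True)
class IntensityTable:
    """Validated per-SNP probe intensities for one hybridization."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in INTENSITY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        bad_strand = set(df["strand"]) - {"sense", "antisense"}
        if bad_strand:
            raise ValueError(f"unknown strand values: {sorted(bad_strand)}")
        dup = df.duplicated(["snp_id", "strand"])
        if dup.any():
            first = df.loc[dup, "snp_id"].iloc[0]
            raise ValueError(f"duplicate (snp_id, strand) rows, e.g. SNP {first!r}")
        for col in ("ref_intensity", "alt_intensity"):
            vals = df[col].to_numpy()
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"non-finite {col}")
            if (vals < 0).any():
                bad = df.loc[df[col] < 0, "snp_id"].iloc[0]
                raise ValueError(f"negative {col} at SNP {bad!r}")
        if (df["pos"].to_numpy() < 1).any():
            raise ValueError("positions must be >= 1 (1-based bp)")
        object.__setattr__(self, "data", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class RegionCall:
    """A contiguous supra-threshold candidate region on one chromosome."""

    chrom: str
    peak_pos: float
    start: float
    end: float
    peak_value: float
    threshold: float

    def __post_init__(self) -> None:
        if not self.start <= self.peak_pos <= self.end:
            raise ValueError("interval must contain the peak")
        if abs(self.peak_value) < self.threshold:
            raise ValueError("peak magnitude must reach the threshold")


def read_intensity_table(path: str | Path) -> IntensityTable:
    """Read and validate an intensity TSV.

    Rows with unparseable numeric fields are dropped and their 1-based
    file line numbers logged; structural violations (missing columns,
    duplicate (snp_id, strand), negative intensities) raise.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in INTENSITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns: {missing}")
    def _parse(value: str) -> float:
        # python's float() is correctly rounded; pandas' fast parser is not
        try:
            return float(value)
        except (TypeError, ValueError):
            return float("nan")

    for col in ("pos", "ref_intensity", "alt_intensity"):
        df[col] = df[col].map(_parse)
    malformed = df[["pos", "ref_intensity", "alt_intensity"]].isna().any(axis=1)
    if malformed.any():
        lines = (df.index[malformed] + 2).tolist()  # +1 header, +1 one-based
        logger.warning("%s: dropped %d malformed rows at lines %s", path, malformed.sum(), lines)
        df = df[~malformed]
    df = df.astype({"pos": np.int64})
    return IntensityTable(df.reset_index(drop=True))


def write_intensity_table(table: IntensityTable, path: str | Path) -> None:
    # %.17g keeps write/read round trips bit-exact for float64 intensities
    table.data.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_marker_list(path: str | Path) -> set[str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "snp_id" not in df.columns:
        raise ValueError(f"{path}: marker list needs an 'snp_id' column")
    return set(df["snp_id"])


def write_marker_list(markers: set[str] | list[str], path: str | Path) -> None:
    pd.DataFrame({"snp_id": sorted(markers)}).to_csv(path, sep="\t", index=False)


def allele_difference(table: IntensityTable) -> pd.DataFrame:
    """Reference minus alternate allele intensity per (SNP, strand).

    Positive values mean preferential hybridization to the
    reference-parent allele.
    """
    df = table.data
    out = df[["snp_id", "chrom", "pos", "strand"]].copy()
    out["diff"] = df["ref_intensity"].to_numpy() - df["alt_intensity"].to_numpy()
    return out


def _strand_trace(delta: pd.DataFrame, span: float) -> SmoothedTrace:
    chroms = {}
    for chrom, grp in delta.groupby("chrom", sort=True):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy(dtype=float)
        raw = grp["delta"].to_numpy(dtype=float)
        if pos.size < 4:
            raise ValueError(f"chromosome {chrom!r} has too few markers ({pos.size}) to smooth")
        chroms[str(chrom)] = ChromosomeTrace(pos, raw, loess_smooth(pos, raw, span))
    return SmoothedTrace(chromosomes=chroms, span=span, units="bp")


def bsa_trace(
    bulkA: IntensityTable,
    bulkB: IntensityTable,
    markers: set[str],
    span: float = 0.25,
) -> dict[str, SmoothedTrace]:
    """Smoothed difference-of-differences traces for two bulks.

    Restricts both tables to the polymorphic marker SNPs, forms
    (bulk A allele difference) - (bulk B allele difference) per SNP and
    strand, sorts by position, and loess-smooths each chromosome.
    Returns ``{"sense": ..., "antisense": ..., "combined": ...}`` where
    the combined trace is the unweighted mean of the two strand traces
    over their shared SNPs.
    """
    if not markers:
        raise ValueError("marker list is empty")
    da = allele_difference(bulkA)
    db = allele_difference(bulkB)
    da = da[da["snp_id"].isin(markers)]
    db = db[db["snp_id"].isin(markers)]
    merged = da.merge(db[["snp_id", "strand", "diff"]], on=["snp_id", "strand"], suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("no marker SNPs shared between the bulk tables")
    merged["delta"] = merged["diff_a"] - merged["diff_b"]

    traces: dict[str, SmoothedTrace] = {}
    for strand in ("sense", "antisense"):
        sub = merged[merged["strand"] == strand]
        if not sub.empty:
            traces[strand] = _strand_trace(sub, span)

    present = [s for s in ("sense", "antisense") if s in traces]
    if len(present) == 2:
        # average the strands over SNPs present on both
        wide = merged.pivot_table(index=["chrom", "pos", "snp_id"], columns="strand", values="delta")
        wide = wide.dropna().reset_index()
        wide["delta"] = (wide["sense"] + wide["antisense"]) / 2.0
        traces["combined"] = _strand_trace(wide, span)
    else:
        traces["combined"] = traces[present[0]]
    return traces


def call_region(trace: SmoothedTrace, thresholds: ThresholdSet) -> list[RegionCall]:
    """Candidate regions where |smoothed| reaches the 95% threshold.

    Each maximal contiguous run of supra-threshold markers yields one
    call; its peak is the marker of largest magnitude in the run.  An
    empty list is a valid outcome.
    """
    thr = thresholds.threshold_95
    calls: list[RegionCall] = []
    for chrom, tr in trace.chromosomes.items():
        above = np.abs(tr.smoothed) >= thr
        if not above.any():
            continue
        # boundaries of contiguous True runs
        edges = np.flatnonzero(np.diff(np.concatenate([[False], above, [False]]).astype(int)))
        for start, stop in zip(edges[::2], edges[1::2]):
            seg = slice(start, stop)
            peak = start + int(np.argmax(np.abs(tr.smoothed[seg])))
            calls.append(
                RegionCall(
                    chrom=chrom,
                    peak_pos=float(tr.positions[peak]),
                    start=float(tr.positions[start]),
                    end=float(tr.positions[stop - 1]),
                    peak_value=float(tr.smoothed[peak]),
                    threshold=thr,
                )
            )
    return calls


def regions_to_frame(calls: list[RegionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "peak_pos": c.peak_pos,
                "start": c.start,
                "end": c.end,
                "peak_value": c.peak_value,
                "threshold": c.threshold,
            }
            for c in calls
        ],
        columns=["chrom", "peak_pos", "start", "end", "peak_value", "threshold"],
    )


def subsample_markers(
    markers: set[str], fraction: float, seed: int | np.random.Generator
) -> set[str]:
    """Uniform random subset of ``round(fraction * |markers|)`` SNPs."""
    if not markers:
        raise ValueError("marker list is empty")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1:
        return set(markers)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ordered = sorted(markers)
    k = int(round(fraction * len(ordered)))
    return set(rng.choice(ordered, size=k, replace=False))


def _bulk_mean_signals(
    freqs: np.ndarray, bank: SignalBank, n_pool: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean allele-difference per SNP for a bulk of ``n_pool`` F2 plants.

    ``freqs`` is the reference-allele frequency per SNP; genotypes are
    drawn per plant under Hardy-Weinberg at that frequency, then signal
    values are resampled from the matching bank pools and averaged.
    """
    n_snps = freqs.size
    p = freqs[:, None]
    u = rng.random((n_snps, n_pool))
    # genotype codes 2/1/0 with probs p^2, 2p(1-p), (1-p)^2
    codes = np.where(u < p**2, 2, np.where(u < p**2 + 2 * p * (1 - p), 1, 0))
    values = np.empty_like(u)
    for code, pool in ((0, bank.bb), (1, bank.ab), (2, bank.aa)):
        mask = codes == code
        values[mask] = pool[rng.integers(0, pool.size, int(mask.sum()))]
    return values.mean(axis=1)


def generate_fixture(
    config: ScenarioConfig,
    region: tuple[str, int, int],
    out_dir: str | Path,
    n_snps: int = 2000,
    marker_fraction: float = 0.8,
    skew: float = 1.0,
    chrom_lengths_bp: dict[str, int] | None = None,
    base_intensity: float = 8.0,
) -> dict[str, Path]:
    """Write a synthetic pair of bulk intensity tables with a planted region.

    Synthetic stand-in for a real bulk-hybridization experiment: SNPs
    are placed uniformly along bp coordinates; inside ``region`` the
    marker SNPs carry an allele-frequency skew of ``skew`` between the
    two bulks (1.0 fixes the bulks for opposite parental alleles), all
    other SNPs are balanced, and non-marker SNPs draw control-probe
    noise.  Bulk sizes follow the scenario's population size and
    selection fraction.  Writes ``bulkA.tsv``, ``bulkB.tsv``,
    ``markers.tsv`` and a ``truth.json`` sidecar recording the planted
    region; returns the paths.
    """
    chrom, start, end = str(region[0]), int(region[1]), int(region[2])
    lengths = dict(chrom_lengths_bp or DEFAULT_CHROM_LENGTHS_BP)
    if chrom not in lengths:
        raise ValueError(f"region chromosome {chrom!r} not in the map")
    if not 0 <= start < end <= lengths[chrom]:
        raise ValueError("invalid region interval")
    if not 0 <= skew <= 1:
        raise ValueError("skew must be in [0, 1]")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(config.seed)
    bank = config.bank or make_synthetic_bank(seed=rng, **config.bank_params)
    n_pool = max(1, int(round(config.selection_fraction * config.population_size)))

    total_bp = sum(lengths.values())
    rows = []
    for name, length in lengths.items():
        k = max(10, int(round(n_snps * length / total_bp)))
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=k, replace=False))
        rows.append(pd.DataFrame({"chrom": name, "pos": pos}))
    snps = pd.concat(rows, ignore_index=True)
    snps["snp_id"] = [f"snp_{c}_{p}" for c, p in zip(snps["chrom"], snps["pos"])]
    is_marker = rng.random(len(snps)) < marker_fraction
    snps["marker"] = is_marker

    in_region = (
        (snps["chrom"] == chrom) & (snps["pos"] >= start) & (snps["pos"] <= end)
    ).to_numpy()
    marker_arr = snps["marker"].to_numpy()

    tables = {}
    for bulk, shift in (("bulkA", +skew / 2), ("bulkB", -skew / 2)):
        strand_frames = []
        for strand in ("sense", "antisense"):
            freqs = np.full(len(snps), 0.5)
            freqs[in_region & marker_arr] = 0.5 + shift
            diffs = _bulk_mean_signals(freqs, bank, n_pool, rng)
            # non-marker SNPs are monomorphic: control-probe noise only
            n_ctl = int((~marker_arr).sum())
            ctl = bank.control[rng.integers(0, bank.control.size, (n_ctl, n_pool))]
            diffs[~marker_arr] = ctl.mean(axis=1)
            frame = snps[["snp_id", "chrom", "pos"]].copy()
            frame["strand"] = strand
            frame["ref_intensity"] = np.maximum(base_intensity + diffs / 2, 0.0)
            frame["alt_intensity"] = np.maximum(base_intensity - diffs / 2, 0.0)
            strand_frames.append(frame)
        tables[bulk] = pd.concat(strand_frames, ignore_index=True)

    paths = {
        "bulkA": out_dir / "bulkA.tsv",
        "bulkB": out_dir / "bulkB.tsv",
        "markers": out_dir / "markers.tsv",
        "truth": out_dir / "truth.json",
    }
    for bulk in ("bulkA", "bulkB"):
        write_intensity_table(IntensityTable(tables[bulk]), paths[bulk])
    write_marker_list(set(snps.loc[snps["marker"], "snp_id"]), paths["markers"])
    paths["truth"].write_text(
        json.dumps(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "skew": skew,
                "n_pool": n_pool,
                "seed": config.seed,
            },
            indent=2,
        )
    )
    return paths
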