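"""Per-marker SNP allele-difference signal models.

A SNP genotyping array carries probes for both alleles of each SNP; the
working signal is the reference-allele probe intensity minus the
alternate-allele probe intensity, so preferential hybridization to the
reference (Col-0-like) allele is positive.  A :class:`SignalBank` holds
pools of such allele-difference values per genotype class — drawn either
from two real parental hybridizations (empirical) or from a synthetic
generator that emulates their shape: two separated, partially
overlapping marker peaks of opposite sign, control probes centred at
zero, and a heterozygote ("pseudo-F1") class built as probe-wise means
of the two parents, distributed about zero.

Signals are assigned to simulated genotypes by resampling the bank pool
matching each genotype class, which reproduces the marginal noise
structure of a real hybridization without modelling probe-specific
affinity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genetic_models import AA, AB, BB, GenotypeMatrix

__all__ = [
    "SignalBank",
    "PoolSignalMatrix",
    "make_synthetic_bank",
    "load_empirical_bank",
    "assign_signals",
    "DEFAULT_BANK_PARAMS",
]

#: Synthetic bank defaults (signal units): marker-class mode, marker-class
#: spread, control spread.  Chosen so the AA/BB modes separate clearly
#: while the tails overlap the control distribution.
DEFAULT_BANK_PARAMS: dict[str, float] = {
    "mu_marker": 1.5,
    "sd_marker": 0.8,
    "sd_control": 0.5,
}

_CLASS_NAMES = {AA: "AA", AB: "AB", BB: "BB"}


@dataclass(frozen=True)
class SignalBank:
    """Pools of allele-difference values per genotype class.

    Attributes
    ----------
    aa, bb, ab
        Allele-difference pools for the homozygous reference, homozygous
        alternate, and heterozygous classes.  The AB pool is the
        pseudo-F1: probe-wise means of paired parent values.
    control
        Pool of differences at non-polymorphic (control) probes.
    provenance
        ``"empirical"`` or ``"synthetic"``.
    strand
        ``"sense"`` or ``"antisense"``; simulations use sense only.
    """

    aa: np.ndarray
    bb: np.ndarray
    ab: np.ndarray
    control: np.ndarray
    provenance: str = "synthetic"
    strand: str = "sense"

    def __post_init__(self) -> None:
        for name in ("aa", "bb", "ab", "control"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size == 0:
                raise ValueError(f"{name} pool must be non-empty")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} pool contains non-finite values")
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)
        # non-strict so that a degenerate all-zero (null-signal) bank is valid
        if not (self.aa.mean() >= 0 >= self.bb.mean()):
            raise ValueError("sign convention violated: need AA pool mean >= 0 >= BB pool mean")
        if self.strand not in ("sense", "antisense"):
            raise ValueError(f"unknown strand {self.strand!r}")
        if self.provenance not in ("empirical", "synthetic"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def pool(self, genotype_code: int) -> np.ndarray:
        try:
            return {AA: self.aa, AB: self.ab, BB: self.bb}[genotype_code]
        except KeyError:
            raise ValueError(f"no pool for genotype code {genotype_code!r}") from None

    def negated(self) -> "SignalBank":
        """Bank with the parent roles swapped (AA/BB exchanged, all signs flipped)."""
        return SignalBank(
            aa=-self.bb,
            bb=-self.aa,
            ab=-self.ab,
            control=-self.control,
            provenance=self.provenance,
            strand=self.strand,
        )

    def to_tsv(self, path: str | Path) -> None:
        """Serialize as a two-column TSV (class, value)."""
        frames = [
            pd.DataFrame({"class": label, "value": arr})
            for label, arr in [
                ("AA", self.aa),
                ("AB", self.ab),
                ("BB", self.bb),
                ("control", self.control),
            ]
        ]
        pd.concat(frames).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, provenance: str = "empirical", strand: str = "sense"
    ) -> "SignalBank":
        df = pd.read_csv(path, sep="\t")
        pools = {label: grp["value"].to_numpy() for label, grp in df.groupby("class")}
        return cls(
            aa=pools["AA"],
            bb=pools["BB"],
            ab=pools["AB"],
            control=pools["control"],
            provenance=provenance,
            strand=strand,
        )


@dataclass(frozen=True)
class PoolSignalMatrix:
    """Individuals x markers allele-difference values for one bulk."""

    values: np.ndarray
    genotypes: GenotypeMatrix

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != self.genotypes.codes.shape:
            raise ValueError("signal matrix shape must match the genotype matrix")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    @property
    def map(self):
        return self.genotypes.map


def make_synthetic_bank(
    mu_marker: float = DEFAULT_BANK_PARAMS["mu_marker"],
    sd_marker: float = DEFAULT_BANK_PARAMS["sd_marker"],
    sd_control: float = DEFAULT_BANK_PARAMS["sd_control"],
    size: int = 20_000,
    seed: int | np.random.Generator = 0,
) -> SignalBank:
    """Generate a synthetic signal bank.

    AA values are Normal(+mu_marker, sd_marker), BB values
    Normal(-mu_marker, sd_marker), controls Normal(0, sd_control), and
    the AB pool is the elementwise mean of paired AA and BB draws — the
    same pseudo-F1 construction used for empirical parent arrays.
    """
    if mu_marker <= 0:
        raise ValueError("mu_marker must be > 0")
    if sd_marker < 0 or sd_control < 0:
        raise ValueError("standard deviations must be >= 0")
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    aa = rng.normal(mu_marker, sd_marker, size)
    bb = rng.normal(-mu_marker, sd_marker, size)
    ab = (aa + bb) / 2.0
    control = rng.normal(0.0, sd_control, size)
    return SignalBank(aa=aa, bb=bb, ab=ab, control=control, provenance="synthetic")


def load_empirical_bank(
    parentA_table: str | Path,
    parentB_table: str | Path,
    marker_list: str | Path,
    strand: str = "sense",
) -> SignalBank:
    """Build a signal bank from two parental hybridization tables.

    The AA pool holds parent A's allele differences at the marker
    (polymorphic) SNPs, the BB pool parent B's, the AB pool their
    probe-wise mean (pseudo-F1), and the control pool the differences of
    both parents at non-marker SNPs.
    """
    from .snp_pipeline import allele_difference, read_intensity_table, read_marker_list

    diff_a = allele_difference(read_intensity_table(parentA_table))
    diff_b = allele_difference(read_intensity_table(parentB_table))
    markers = read_marker_list(marker_list)
    if not markers:
        raise ValueError("marker list is empty")
    a = diff_a[diff_a["strand"] == strand].set_index("snp_id")["diff"]
    b = diff_b[diff_b["strand"] == strand].set_index("snp_id")["diff"]
    shared = a.index.intersection(b.index)
    if shared.empty:
        raise ValueError("parent tables share no SNPs")
    a, b = a.loc[shared], b.loc[shared]
    is_marker = shared.isin(markers)
    if not is_marker.any():
        raise ValueError("no marker SNPs present in the parent tables")
    aa = a[is_marker].to_numpy()
    bb = b[is_marker].to_numpy()
    ab = (aa + bb) / 2.0
    control = np.concatenate([a[~is_marker].to_numpy(), b[~is_marker].to_numpy()])
    if control.size == 0:
        raise ValueError("no control (non-marker) SNPs present")
    return SignalBank(aa=aa, bb=bb, ab=ab, control=control, provenance="empirical", strand=strand)


def assign_signals(
    genotypes: GenotypeMatrix,
    bank: SignalBank,
    seed: int | np.random.Generator,
) -> PoolSignalMatrix:
    """Draw an allele-difference value for every (individual, marker) cell.

    Each cell is an independent uniform draw, with replacement, from the
    bank pool matching its genotype class (sense strand).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = genotypes.codes
    values = np.empty(codes.shape, dtype=float)
    # iterate classes in fixed order so the draw stream is reproducible
    for code in (BB, AB, AA):
        mask = codes == code
        n = int(mask.sum())
        if n:
            pool = bank.pool(code)
            values[mask] = pool[rng.integers(0, pool.size, n)]
    return PoolSignalMatrix(values=values, genotypes=genotypes)
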