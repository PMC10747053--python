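"""In-memory genotype container and plain-text VCF writing.

Genotypes are stored as alternate-allele dosages (0, 1, 2) in an int8 matrix
of shape (samples, sites); ``-1`` marks a missing call.  Site coordinates keep
the VCF 1-based convention; all interval outputs elsewhere in the package are
0-based half-open (BED).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sojapop.errors import SojapopError

MISSING = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-SNP dosage matrix.

    Parameters
    ----------
    samples : list of str
        Ordered sample identifiers.
    sites : pandas.DataFrame
        One row per site with columns ``chrom``, ``pos`` (1-based), ``ref``,
        ``alt``; sorted by (chrom, pos) with no duplicate coordinates.
    dosage : numpy.ndarray of int8, shape (n_samples, n_sites)
        Alternate-allele dosage; ``-1`` is missing.
    chrom_lengths : dict
        Contig name -> length in bp (from VCF ``##contig`` headers when read
        from disk; falls back to the maximum observed position).
    """

    samples: list
    sites: pd.DataFrame
    dosage: np.ndarray
    chrom_lengths: dict = field(default_factory=dict)

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise SojapopError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        self.sites = self.sites.reset_index(drop=True)
        if not self.chrom_lengths:
            self.chrom_lengths = {
                str(c): int(g["pos"].max())
                for c, g in self.sites.groupby("chrom", sort=False)
            }

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def allele_counts(self, sample_idx=None):
        """Per-site (ref_count, alt_count) over non-missing alleles.

        ``sample_idx`` restricts to a subset of rows (e.g. one group).
        """
        d = self.dosage if sample_idx is None else self.dosage[sample_idx]
        obs = d != MISSING
        n_alleles = 2 * obs.sum(axis=0)
        alt = np.where(obs, d, 0).sum(axis=0)
        return n_alleles - alt, alt

    def alt_freq(self, sample_idx=None) -> np.ndarray:
        ref, alt = self.allele_counts(sample_idx)
        tot = ref + alt
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)

    def maf(self) -> np.ndarray:
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)

    def missing_fraction(self) -> np.ndarray:
        return self.missing_mask().mean(axis=0)

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx],
            chrom_lengths=dict(self.chrom_lengths),
        )

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            sites=self.sites.copy(),
            dosage=self.dosage[idx],
            chrom_lengths=dict(self.chrom_lengths),
        )

    def sample_index(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as exc:
            raise SojapopError(f"unknown sample id {exc.args[0]!r}") from None


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with contig headers and GT-only FORMAT."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sojapop\n")
        for chrom, length in gm.chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={int(length)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        chroms = gm.sites["chrom"].to_numpy()
        poss = gm.sites["pos"].to_numpy()
        refs = gm.sites["ref"].to_numpy()
        alts = gm.sites["alt"].to_numpy()
        for j in range(gm.n_sites):
            gts = "\t".join(_GT_STRINGS[int(g)] for g in gm.dosage[:, j])
            fh.write(
                f"{chroms[j]}\t{poss[j]}\t.\t{refs[j]}\t{alts[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )
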