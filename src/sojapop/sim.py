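"""Synthetic wild-soybean-style data with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: three latitude-separated population groups with Balding–Nichols
allele-frequency divergence, predominant selfing (high F_IS), within-group
isolation by distance, latitude-driven environmental clines (annual mean
temperature and precipitation both decrease with increasing latitude), loci whose
frequencies track the environment on the logistic scale, and sweep regions of
locally reduced diversity in one group.

One :class:`numpy.random.Generator` seeded once drives every draw, in a fixed
documented order (positions, geography, environment, ancestral and group
frequencies, sweep placement, adaptive-locus placement, location frequencies,
genotypes, phenotypes), so a given seed reproduces byte-identical output
files on any platform.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sojapop.errors import SojapopError
from sojapop.genotypes import GenotypeMatrix, write_vcf

GROUP_NAMES = ("SR", "CR", "NER")  # south to north
# latitude band centres (deg N) spanning ~22-48 N, and longitude centres (deg E)
_LAT_CENTERS = (25.0, 35.0, 45.0)
_LON_CENTERS = (112.0, 116.0, 126.0)

# internal scales (not exposed: they define the study conditions, not dials)
# the within-group IBD gradient is a refinement of the group-level structure;
# it must stay well below typical adaptive env effects or it would mimic them
_IBD_LOGIT_SD = 0.1       # per-SNP latitudinal gradient scale within groups
_LOC_NOISE_SD = 0.05      # residual per-location logit noise
_FREQ_CLAMP = (0.01, 0.99)

_PHENO_TRAITS = {
    "flower_color": (("Purple",), ((1.0,), (1.0,), (1.0,))),
    "pubescence_type": (("Erect", "Oblique", "Flat"),
                        ((0.30, 0.50, 0.20), (0.00, 0.85, 0.15), (0.00, 0.45, 0.55))),
    "pod_color": (("Brown", "Dark brown", "Black"),
                  ((0.45, 0.50, 0.05), (0.35, 0.45, 0.20), (0.15, 0.45, 0.40))),
}


@dataclass
class SimConfig:
    """Simulation parameters; defaults emulate a 3-group, 15-location,
    75-accession GBS panel at desk scale."""

    n_groups: int = 3
    locations_per_group: int = 5
    samples_per_location: int = 5
    n_chrom: int = 4
    chrom_length: int = 10_000_000
    n_snps: int = 20_000
    fst_divergence: float = 0.30
    selfing_fis: float = 0.95
    n_sweeps: int = 3
    sweep_width: int = 1_000_000
    sweep_diversity_reduction: float = 0.9
    n_adaptive_loci: int = 30
    env_effect: float = 1.0
    env_noise_sd: float = 2.0
    seed: int = 0

    def validate(self):
        counts = {
            "n_groups": self.n_groups,
            "locations_per_group": self.locations_per_group,
            "samples_per_location": self.samples_per_location,
            "n_chrom": self.n_chrom,
            "chrom_length": self.chrom_length,
            "n_snps": self.n_snps,
            "n_sweeps": self.n_sweeps,
            "sweep_width": self.sweep_width,
            "n_adaptive_loci": self.n_adaptive_loci,
        }
        for name, v in counts.items():
            if v < 0:
                raise SojapopError(f"{name} must be >= 0, got {v}")
        if not 0.0 < self.fst_divergence < 1.0:
            raise SojapopError("fst_divergence must lie in (0, 1)")
        if not 0.0 <= self.selfing_fis <= 1.0:
            raise SojapopError("selfing_fis must lie in [0, 1]")
        if not 0.0 < self.sweep_diversity_reduction <= 1.0:
            raise SojapopError("sweep_diversity_reduction must lie in (0, 1]")
        n_samples = self.n_groups * self.locations_per_group * self.samples_per_location
        if n_samples == 0:
            raise SojapopError("simulation needs at least one sample")
        if self.n_sweeps > 0 and self.n_snps < 2 * self.n_sweeps:
            raise SojapopError(
                f"n_snps={self.n_snps} too small to carry {self.n_sweeps} sweeps "
                "(need >= 2 sites per sweep)"
            )
        if self.n_sweeps > 0 and self.sweep_width > self.chrom_length:
            raise SojapopError("sweep_width exceeds chrom_length")


@dataclass
class SimTruth:
    """Planted signals: sweep intervals (0-based half-open), adaptive loci,
    sample group/location assignments and location coordinates."""

    sweep_regions: list        # (chrom, start, end, group)
    adaptive_loci: list        # (chrom, pos_1based, env_name, effect)
    group_assignments: dict    # sample -> group
    location_coords: dict      # location -> (lat, lon)


@dataclass
class SimResult:
    genotypes: GenotypeMatrix
    metadata: pd.DataFrame     # sample, location, latitude, longitude, group
    environment: pd.DataFrame  # location, annual_mean_temp, annual_precip
    phenotypes: pd.DataFrame
    truth: SimTruth
    config: SimConfig = field(repr=False, default=None)


def _diversity_shrink(p: np.ndarray, reduction: float) -> np.ndarray:
    """Move frequencies toward the nearest fixation so heterozygosity
    p(1-p) is scaled by (1 - reduction)."""
    h = (1.0 - reduction) * p * (1.0 - p)
    root = 0.5 * (1.0 - np.sqrt(np.maximum(0.0, 1.0 - 4.0 * h)))
    return np.where(p <= 0.5, root, 1.0 - root)


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate(config: SimConfig) -> SimResult:
    """Generate genotypes, geography, environment, phenotypes and truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, Lg, S = config.n_groups, config.locations_per_group, config.samples_per_location
    n_loc = G * Lg
    m = config.n_snps

    # 1. chromosome map and SNP positions
    chroms = [f"Gs{c + 1:02d}" for c in range(config.n_chrom)]
    chrom_lengths = {c: config.chrom_length for c in chroms}
    per_chrom = np.full(config.n_chrom, m // config.n_chrom)
    per_chrom[: m % config.n_chrom] += 1
    site_rows = []
    for c, k in zip(chroms, per_chrom):
        pos = np.sort(rng.choice(config.chrom_length - 1, size=k, replace=False)) + 1
        site_rows.append(pd.DataFrame({"chrom": c, "pos": pos}))
    sites = pd.concat(site_rows, ignore_index=True)
    ref = rng.choice(np.array(list("ACGT")), size=m)
    # alt differs from ref deterministically
    shift = rng.integers(1, 4, size=m)
    bases = np.array(list("ACGT"))
    base_idx = {b: i for i, b in enumerate(bases)}
    alt = bases[(np.vectorize(base_idx.get)(ref) + shift) % 4]
    sites["ref"], sites["alt"] = ref, alt

    # 2. geography: latitude-separated group clusters
    loc_group = np.repeat(np.arange(G), Lg)
    lat_c = np.array([_LAT_CENTERS[g % 3] + 10.0 * (g // 3) for g in range(G)])
    lon_c = np.array([_LON_CENTERS[g % 3] for g in range(G)])
    # survey-style placement: sites cover each group's latitude band evenly
    # (span ~7 deg, matching ~22-48 N overall) with small positional jitter
    if Lg > 1:
        band = np.tile(np.linspace(-3.5, 3.5, Lg), G)
    else:
        band = np.zeros(n_loc)
    lat = lat_c[loc_group] + band + rng.normal(0.0, 0.5, n_loc)
    lon = lon_c[loc_group] + rng.normal(0.0, 3.0, n_loc)
    loc_names = [f"L{i + 1:02d}" for i in range(n_loc)]

    # 3. environment: temperature and precipitation decrease with latitude
    # temperature deviations are elevation-dominated locally, hence the
    # wider scatter relative to the latitudinal lapse than precipitation has
    temp = 28.0 - 0.7 * (lat - 20.0) + rng.normal(0.0, 1.5 * config.env_noise_sd, n_loc)
    precip = 1800.0 - 45.0 * (lat - 20.0) + rng.normal(
        0.0, 100.0 * config.env_noise_sd, n_loc
    )
    environment = pd.DataFrame(
        {"location": loc_names,
         "annual_mean_temp": np.round(temp, 3),
         "annual_precip": np.round(precip, 2)}
    )

    # 4. ancestral and Balding-Nichols group frequencies
    p_anc = rng.uniform(0.05, 0.95, m)
    F = config.fst_divergence
    a, b = p_anc * (1.0 - F) / F, (1.0 - p_anc) * (1.0 - F) / F
    p_group = rng.beta(np.tile(a, (G, 1)), np.tile(b, (G, 1)))  # (G, m)

    # 5. sweep placement (non-overlapping) and frequency shrink in one group
    sweep_regions = []
    occupied = {c: [] for c in chroms}
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    for s in range(config.n_sweeps):
        grp = s % G
        for _ in range(200):
            c = chroms[int(rng.integers(0, config.n_chrom))]
            start = int(rng.integers(0, config.chrom_length - config.sweep_width + 1))
            end = start + config.sweep_width
            if all(end <= s0 or start >= e0 for s0, e0 in occupied[c]):
                break
        else:
            raise SojapopError("could not place non-overlapping sweep regions")
        occupied[c].append((start, end))
        sweep_regions.append((c, start, end, GROUP_NAMES[grp % 3] if G <= 3 else f"G{grp + 1}"))
        in_sweep = (chrom_arr == c) & (pos_arr - 1 >= start) & (pos_arr - 1 < end)
        p_group[grp, in_sweep] = _diversity_shrink(
            p_group[grp, in_sweep], config.sweep_diversity_reduction
        )
    p_group = np.clip(p_group, *_FREQ_CLAMP)

    group_names = [GROUP_NAMES[g] if G <= 3 else f"G{g + 1}" for g in range(G)]

    # 6. adaptive loci outside sweeps, alternating environment variables
    # (selection acts on the physical environment; latitude is only a proxy
    # coordinate for the association scan, so no loci are planted on it)
    env_vars = ("annual_mean_temp", "annual_precip")
    in_any_sweep = np.zeros(m, dtype=bool)
    for c, s0, e0, _ in sweep_regions:
        in_any_sweep |= (chrom_arr == c) & (pos_arr - 1 >= s0) & (pos_arr - 1 < e0)
    free = np.flatnonzero(~in_any_sweep)
    if config.n_adaptive_loci > len(free):
        raise SojapopError("not enough non-sweep SNPs for the adaptive loci")
    adaptive_idx = np.sort(rng.choice(free, size=config.n_adaptive_loci, replace=False))
    adaptive_env = [env_vars[i % len(env_vars)] for i in range(config.n_adaptive_loci)]
    env_values = {"annual_mean_temp": temp, "annual_precip": precip, "latitude": lat}
    z_env = {
        k: (v - v.mean()) / v.std() if v.std() > 0 else np.zeros_like(v)
        for k, v in env_values.items()
    }

    # 7. per-location frequencies: IBD gradient + adaptive shift on logit scale
    z_lat = np.zeros(n_loc)
    for g in range(G):
        sel = loc_group == g
        sd = lat[sel].std()
        z_lat[sel] = (lat[sel] - lat[sel].mean()) / (sd if sd > 0 else 1.0)
    grad = rng.normal(0.0, _IBD_LOGIT_SD, (G, m))          # per group x SNP
    loc_noise = rng.normal(0.0, _LOC_NOISE_SD, (n_loc, m))
    logit_loc = _logit(p_group[loc_group]) + grad[loc_group] * z_lat[:, None] + loc_noise
    # at adaptive loci selection overwhelms drift: the local frequency tracks
    # the environment around the ancestral frequency instead of the drifted
    # group frequency (keeps the dose-response away from the clamp bounds)
    for si, ev in zip(adaptive_idx, adaptive_env):
        logit_loc[:, si] = (
            _logit(p_anc[si])
            + grad[loc_group, si] * z_lat
            + loc_noise[:, si]
            + config.env_effect * z_env[ev]
        )
    p_loc = np.clip(_expit(logit_loc), *_FREQ_CLAMP)        # (n_loc, m)

    # 8. genotypes with inbreeding F_IS
    fis = config.selfing_fis
    sample_loc = np.repeat(np.arange(n_loc), S)
    n_samples = len(sample_loc)
    q = p_loc[sample_loc]                                   # (n_samples, m)
    het = q * (1.0 - q)
    p_hom_alt = q * q + fis * het
    p_het = 2.0 * het * (1.0 - fis)
    u = rng.random((n_samples, m))
    dosage = np.full((n_samples, m), 0, dtype=np.int8)
    dosage[u < p_hom_alt + p_het] = 1
    dosage[u < p_hom_alt] = 2

    sample_names = [f"GS{i + 1:03d}" for i in range(n_samples)]
    metadata = pd.DataFrame(
        {"sample": sample_names,
         "location": [loc_names[l] for l in sample_loc],
         "latitude": np.round(lat[sample_loc], 4),
         "longitude": np.round(lon[sample_loc], 4),
         "group": [group_names[loc_group[l]] for l in sample_loc]}
    )

    # 9. categorical phenotypes with group-specific category frequencies
    pheno_cols = {"accession": sample_names, "group": metadata["group"].tolist()}
    sample_group = loc_group[sample_loc]
    for trait, (cats, probs) in _PHENO_TRAITS.items():
        probs = np.asarray(probs)
        draws = np.empty(n_samples, dtype=object)
        for g in range(G):
            sel = sample_group == g
            draws[sel] = rng.choice(np.array(cats, dtype=object),
                                    size=int(sel.sum()), p=probs[g % 3])
        pheno_cols[trait] = draws
    phenotypes = pd.DataFrame(pheno_cols)

    gm = GenotypeMatrix(sample_names, sites, dosage, chrom_lengths)
    truth = SimTruth(
        sweep_regions=sweep_regions,
        adaptive_loci=[
            (chrom_arr[si], int(pos_arr[si]), ev, config.env_effect)
            for si, ev in zip(adaptive_idx, adaptive_env)
        ],
        group_assignments=dict(zip(sample_names, metadata["group"])),
        location_coords={n: (float(round(la, 4)), float(round(lo, 4)))
                         for n, la, lo in zip(loc_names, lat, lon)},
    )
    return SimResult(gm, metadata, environment, phenotypes, truth, config)


def write_outputs(result: SimResult, outdir) -> dict:
    """Write VCF, metadata/environment/phenotype TSVs, truth BED + TSV and the
    effective config; returns the path map.  Deterministic given the seed."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "metadata": out / "metadata.tsv",
        "environment": out / "environment.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "sweeps_bed": out / "truth_sweeps.bed",
        "adaptive_tsv": out / "truth_adaptive_loci.tsv",
        "config": out / "sim_config.txt",
    }
    write_vcf(result.genotypes, paths["vcf"])
    result.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    result.environment.to_csv(paths["environment"], sep="\t", index=False)
    result.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    with open(paths["sweeps_bed"], "w") as fh:
        for c, s, e, g in result.truth.sweep_regions:
            fh.write(f"{c}\t{s}\t{e}\t{g}\n")
    pd.DataFrame(result.truth.adaptive_loci,
                 columns=["chrom", "pos", "env", "effect"]).to_csv(
        paths["adaptive_tsv"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        for f in dataclasses.fields(result.config):
            fh.write(f"{f.name}={getattr(result.config, f.name)}\n")
    return {k: str(v) for k, v in paths.items()}
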