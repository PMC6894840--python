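"""Synthetic barcode datasets and synthetic trochospiral shells.

Two generators provide test beds with the statistical structure the
downstream analyses assume:

* :func:`generate_barcode_dataset` plants a three-level hierarchy of SSU
  rDNA-like sequence motifs (morphospecies >> genotype >> basegroup) with
  intra-individual rRNA copy variants, replicate observations, partial
  low-quality reads and station metadata, and returns a truth table
  mapping every read to its planted taxon.
* :func:`generate_shell` grows a log-spiral trochospiral shell chamber by
  chamber and returns the chamber series (volumes, centroids, H, L) from
  which Raupian coiling parameters can be re-derived.

``study_barcode_dataset`` and ``study_shell_configs`` instantiate the
generators with the design of the published *Globigerinoides* survey
(morphospecies/genotype/basegroup counts, replicate structure, chamber
counts and proloculus sizes) so that the full pipeline can be exercised
end to end without the deposited raw data.

All randomness flows through :class:`numpy.random.Generator` (PCG64)
seeded from the config; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "BarcodeSimConfig",
    "ShellSimConfig",
    "generate_barcode_dataset",
    "generate_shell",
    "generate_environment_table",
    "study_barcode_dataset",
    "study_shell_configs",
    "ENV_VARIABLES",
]

NUCLEOTIDES = np.array(list("ACGT"))

#: environmental variables carried by the ecology stage
ENV_VARIABLES = ("SST", "MLS", "CHL", "POC", "PROD")

#: plausible open-ocean baselines per variable (degC, psu, mg m-3, mg m-3,
#: mgC m-2 d-1) and between-station standard deviations
_ENV_BASELINE = {
    "SST": (25.0, 2.0),
    "MLS": (35.5, 0.5),
    "CHL": (0.15, 0.05),
    "POC": (40.0, 10.0),
    "PROD": (450.0, 120.0),
}


@dataclass(frozen=True)
class BarcodeSimConfig:
    """Parameters of the hierarchical barcode simulator.

    ``divergence_per_level`` gives the expected substitution fraction on
    the branch leading to each morphospecies, genotype and basegroup
    respectively and must be strictly decreasing (the barcode-gap
    structure the delimitation stage exploits).
    """

    n_morphospecies: int = 3
    genotypes_per_morphospecies: int = 2
    basegroups_per_genotype: int = 2
    divergence_per_level: tuple[float, float, float] = (0.08, 0.02, 0.004)
    intra_individual_variants: int = 0
    variant_divergence: float = 0.001
    seqs_per_taxon: int = 5
    partial_fraction: float = 0.0
    n_stations: int = 10
    seq_length: int = 1000
    env_offsets: dict | None = None
    seed: int = 0

    def validate(self) -> None:
        lv = self.divergence_per_level
        if not (lv[0] > lv[1] > lv[2] >= 0):
            raise ValueError(
                "divergence_per_level must be strictly decreasing "
                f"(morphospecies > genotype > basegroup), got {lv}"
            )
        for name in ("n_morphospecies", "genotypes_per_morphospecies",
                     "basegroups_per_genotype", "seqs_per_taxon",
                     "n_stations", "seq_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.partial_fraction <= 1.0:
            raise ValueError("partial_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ShellSimConfig:
    """Generative Raup parameters for the trochospiral shell simulator.

    W_true is the whorl expansion rate per full revolution, T_true the
    translation rate dz/dr, D_true the relative distance of the
    generating curve from the coiling axis and S_true the chamber aspect
    ratio H/L.  Chamber volumes follow r^3 scaling unless
    ``volume_growth`` pins an explicit per-chamber multiplicative ratio.
    """

    W_true: float = 2.0
    T_true: float = 0.5
    D_true: float = 0.2
    S_true: float = 1.0
    proloculus_volume: float = 1000.0
    n_chambers: int = 15
    angular_increment: float = 2.0 * math.pi / 4.0
    kummerform: bool = False
    kummerform_factor: float = 0.6
    deuteroconch_ratio: float | None = None
    volume_growth: float | None = None
    noise_sd: float = 0.0
    seed: int = 0
    specimen_id: str = "synthetic"

    def validate(self) -> None:
        if self.n_chambers < 2:
            raise ValueError("n_chambers must be >= 2")
        if self.proloculus_volume <= 0:
            raise ValueError("proloculus_volume must be > 0")
        if not 0.0 < self.angular_increment <= math.pi:
            raise ValueError("angular_increment must lie in (0, pi]")
        if self.W_true <= 0:
            raise ValueError("W_true must be > 0")
        if not 0.0 <= self.D_true < 1.0:
            raise ValueError("D_true must lie in [0, 1)")


def _mutate(rng: np.random.Generator, seq: np.ndarray, divergence: float) -> np.ndarray:
    """Star-like substitution of a fixed expected fraction of sites."""
    n_sub = int(round(divergence * seq.size))
    if n_sub == 0:
        return seq.copy()
    out = seq.copy()
    pos = rng.choice(seq.size, size=n_sub, replace=False)
    for p in pos:
        choices = NUCLEOTIDES[NUCLEOTIDES != out[p]]
        out[p] = rng.choice(choices)
    return out


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(NUCLEOTIDES, size=length)


def _station_table(rng: np.random.Generator, n_stations: int) -> pd.DataFrame:
    lat = np.round(rng.uniform(-40.0, 40.0, n_stations), 3)
    lon = np.round(rng.uniform(-179.0, 179.0, n_stations), 3)
    months = rng.integers(1, 13, n_stations)
    years = rng.integers(1995, 2016, n_stations)
    return pd.DataFrame(
        {
            "station_id": [f"ST{i + 1:03d}" for i in range(n_stations)],
            "latitude": lat,
            "longitude": lon,
            "date": [f"{y:04d}-{m:02d}-15" for y, m in zip(years, months)],
            "depth_min": 0,
            "depth_max": rng.integers(20, 700, n_stations),
        }
    )


def _emit_records(plan, stations, rng, partial_fraction, seq_length,
                  id_start=0):
    """Turn an observation plan into sequence-record and truth rows.

    ``plan`` rows: (morphospecies, genotype, basegroup, basetype, motif,
    individual_id, n_reads, source).
    """
    seq_rows, truth_rows = [], []
    n_st = len(stations)
    counter = id_start
    for morpho, geno, bg, bt, motif, indiv, n_reads, source in plan:
        st = stations.iloc[rng.integers(0, n_st)]
        for _ in range(n_reads):
            counter += 1
            sid = f"SEQ{counter:05d}"
            seq = "".join(motif)
            quality = "curated"
            if partial_fraction > 0 and rng.random() < partial_fraction:
                quality = "partial"
                keep = rng.integers(seq_length // 4, 3 * seq_length // 4)
                if rng.random() < 0.5:  # primer-limited prefix
                    seq = seq[:keep]
                else:
                    seq = seq[-keep:]
            seq_rows.append(
                {
                    "sequence_id": sid,
                    "individual_id": indiv,
                    "station_id": st["station_id"],
                    "date": st["date"],
                    "latitude": st["latitude"],
                    "longitude": st["longitude"],
                    "depth_min": st["depth_min"],
                    "depth_max": st["depth_max"],
                    "morphospecies": morpho,
                    "quality": quality,
                    "source": source,
                    "sequence": seq,
                }
            )
            truth_rows.append(
                {
                    "sequence_id": sid,
                    "morphospecies": morpho,
                    "genotype": geno,
                    "basegroup": bg,
                    "basetype": bt,
                }
            )
    return pd.DataFrame(seq_rows), pd.DataFrame(truth_rows)


def generate_barcode_dataset(config: BarcodeSimConfig):
    """Simulate a replicated barcode survey with a planted taxonomy.

    Returns ``(records, stations, truth)`` where ``records`` holds one
    row per read (schema of the metadata TSV plus the sequence itself),
    ``stations`` the station table and ``truth`` the planted
    morphospecies/genotype/basegroup/basetype of every read.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    root = _random_seq(rng, config.seq_length)
    stations = _station_table(rng, config.n_stations)

    d_ms, d_gt, d_bg = config.divergence_per_level
    plan = []
    indiv_counter = 0
    for m in range(config.n_morphospecies):
        ms_seq = _mutate(rng, root, d_ms)
        ms_name = f"morphospecies_{m + 1}"
        for g in range(config.genotypes_per_morphospecies):
            gt_seq = _mutate(rng, ms_seq, d_gt)
            gt_name = f"{ms_name}/genotype_{g + 1}"
            for b in range(config.basegroups_per_genotype):
                bg_seq = _mutate(rng, gt_seq, d_bg)
                bg_name = f"{gt_name}/basegroup_{b + 1}"
                # designated taxon: first basegroup of first genotype of
                # each morphospecies carries co-occurring copy variants
                variants = [bg_seq]
                if config.intra_individual_variants > 1 and g == 0 and b == 0:
                    for _ in range(config.intra_individual_variants - 1):
                        variants.append(
                            _mutate(rng, bg_seq, config.variant_divergence)
                        )
                if len(variants) == 1:
                    for _ in range(config.seqs_per_taxon):
                        indiv_counter += 1
                        plan.append(
                            (ms_name, gt_name, bg_name,
                             f"{bg_name}/bt_1", variants[0],
                             f"IND{indiv_counter:04d}", 1, "direct")
                        )
                else:
                    # each of two cloned individuals yields every variant
                    # at least twice -> every variant replicated >= 3x
                    n_clone_ind = max(2, math.ceil(config.seqs_per_taxon / 2))
                    for _ in range(n_clone_ind):
                        indiv_counter += 1
                        for vi, vseq in enumerate(variants):
                            plan.append(
                                (ms_name, gt_name, bg_name,
                                 f"{bg_name}/bt_{vi + 1}", vseq,
                                 f"IND{indiv_counter:04d}", 2, "clone")
                            )
    records, truth = _emit_records(
        plan, stations, rng, config.partial_fraction, config.seq_length
    )
    return records, stations, truth


def generate_environment_table(
    stations: pd.DataFrame,
    env_offsets: dict | None = None,
    seed: int = 0,
    taxon_of_station: dict | None = None,
) -> pd.DataFrame:
    """Draw per-station environmental records (SST, MLS, CHL, POC, PROD).

    ``env_offsets`` maps taxon -> {variable: mean shift}; stations are
    attributed to taxa through ``taxon_of_station``.  Unknown variable
    names are rejected.  Output is a long table with one row per
    station x variable, carrying the station month and coordinates so it
    can serve as the lookup table of the ecology stage.
    """
    if stations.empty:
        raise ValueError("no stations to attach environment to")
    env_offsets = env_offsets or {}
    for taxon, shifts in env_offsets.items():
        for var in shifts:
            if var not in ENV_VARIABLES:
                raise ValueError(f"unknown environmental variable: {var!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for _, st in stations.iterrows():
        month = int(str(st["date"])[5:7])
        taxon = (taxon_of_station or {}).get(st["station_id"])
        for var in ENV_VARIABLES:
            mean, sd = _ENV_BASELINE[var]
            shift = env_offsets.get(taxon, {}).get(var, 0.0)
            value = rng.normal(mean + shift, sd)
            if var in ("CHL", "POC", "PROD"):
                value = max(value, 0.0)
            rows.append(
                {
                    "station_id": st["station_id"],
                    "latitude": st["latitude"],
                    "longitude": st["longitude"],
                    "month": month,
                    "variable": var,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# shells


def generate_shell(config: ShellSimConfig) -> pd.DataFrame:
    """Grow a synthetic trochospiral shell and return its chamber series.

    Centroids lie on a logarithmic helicospiral: the radius grows by a
    factor W_true per full revolution, the height advances with slope
    T_true in dz/dr, chamber extents follow D_true and S_true.  Columns
    match the chamber-series CSV contract: chamber_index, volume_um3,
    x_um, y_um, z_um, major_axis_um, H_um, L_um.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_chambers
    theta = np.arange(n) * config.angular_increment
    # proloculus radius scaled from its volume so geometry and volume agree
    r0 = (3.0 * config.proloculus_volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    r = r0 * config.W_true ** (theta / (2.0 * math.pi))
    z = config.T_true * (r - r0)
    if config.noise_sd > 0:
        r = r * np.exp(rng.normal(0.0, config.noise_sd, n))
        z = z + rng.normal(0.0, config.noise_sd, n) * r0

    volumes = np.empty(n)
    volumes[0] = config.proloculus_volume
    if config.volume_growth is not None:
        g = config.volume_growth
        start = 1
        if config.deuteroconch_ratio is not None and n > 1:
            volumes[1] = volumes[0] * config.deuteroconch_ratio
            start = 2
        for k in range(start, n):
            volumes[k] = volumes[k - 1] * g
    else:
        volumes = config.proloculus_volume * (r / r0) ** 3
        if config.deuteroconch_ratio is not None and n > 1:
            volumes[1] = volumes[0] * config.deuteroconch_ratio
    if config.noise_sd > 0:
        volumes = volumes * np.exp(rng.normal(0.0, config.noise_sd, n))
        volumes[0] = config.proloculus_volume
    if config.kummerform:
        volumes[-1] = volumes[-2] * config.kummerform_factor

    # chamber extents from the planted D and S
    L = 2.0 * r * (1.0 - config.D_true) / (1.0 + config.D_true)
    H = config.S_true * L
    x = r * np.cos(theta)
    y = r * np.sin(theta)
    return pd.DataFrame(
        {
            "specimen_id": config.specimen_id,
            "chamber_index": np.arange(1, n + 1),
            "volume_um3": volumes,
            "x_um": x,
            "y_um": y,
            "z_um": z,
            "major_axis_um": np.maximum(H, L),
            "H_um": H,
            "L_um": L,
        }
    )


# ---------------------------------------------------------------------------
# study-structured instantiations


def _sphere_volume(diameter_um: float) -> float:
    return (4.0 / 3.0) * math.pi * (diameter_um / 2.0) ** 3


#: per-specimen design of the CT-scanned shells: chamber count,
#: proloculus diameter (um), kummerform terminal chamber, W, T,
#: chambers per whorl
_STUDY_SHELLS = {
    "G_ruber_albus": dict(n=15, proloculus=12.5, kummerform=False, W=1.45,
                          T=0.45, per_whorl=4.3),
    "G_rubescens": dict(n=17, proloculus=11.0, kummerform=True, W=1.35,
                        T=0.40, per_whorl=5.0),
    "G_tenellus": dict(n=16, proloculus=10.0, kummerform=True, W=1.40,
                       T=0.42, per_whorl=5.0),
    "G_elongatus": dict(n=18, proloculus=9.0, kummerform=True, W=1.40,
                        T=0.45, per_whorl=5.0),
    "G_conglobatus": dict(n=18, proloculus=17.0, kummerform=True, W=1.60,
                          T=0.50, per_whorl=4.5),
}


def _ruber_volume_growth(n: int, deuteroconch_ratio: float,
                         last3_fraction: float) -> float:
    """Per-chamber volume ratio giving the target last-3-chamber share.

    Volumes are v1, d*v1, d*v1*g, ..., d*v1*g^(n-2); solve for g such
    that the last three chambers hold ``last3_fraction`` of the total.
    """

    def frac(g):
        v = np.empty(n)
        v[0] = 1.0
        v[1] = deuteroconch_ratio
        for k in range(2, n):
            v[k] = v[k - 1] * g
        return v[-3:].sum() / v.sum() - last3_fraction

    return brentq(frac, 1.2, 10.0, xtol=1e-12)


def study_shell_configs(seed: int = 0) -> dict[str, ShellSimConfig]:
    """Shell configs emulating the five CT-scanned study specimens.

    Synthetic stand-ins: chamber counts, proloculus diameters and
    kummerform flags follow the published description; the *G. ruber*
    volume-growth ratio is solved so that its three final chambers hold
    94% of the total inner volume.
    """
    configs = {}
    for i, (species, p) in enumerate(_STUDY_SHELLS.items()):
        vol_growth = None
        if species == "G_ruber_albus":
            vol_growth = _ruber_volume_growth(p["n"], 0.75, 0.94)
        elif p["kummerform"]:
            vol_growth = 1.6  # steady logarithmic growth before terminal dip
        configs[species] = ShellSimConfig(
            W_true=p["W"],
            T_true=p["T"],
            D_true=0.25,
            S_true=1.0,
            proloculus_volume=_sphere_volume(p["proloculus"]),
            n_chambers=p["n"],
            angular_increment=2.0 * math.pi / p["per_whorl"],
            kummerform=p["kummerform"],
            deuteroconch_ratio=0.75,
            volume_growth=vol_growth,
            noise_sd=0.0,
            seed=seed + i,
            specimen_id=species,
        )
    return configs


#: planted molecular taxonomy of the study: morphospecies ->
#: genotype -> basegroup -> number of basetypes
_STUDY_TAXONOMY = {
    "G_rubescens": {"a": {"1": 3}},
    "G_ruber_albus": {"a": {"1": 1, "2": 1}, "b": {"1": 1, "2": 1},
                      "c": {"1": 1}},
    "G_ruber_ruber": {"a": {"1": 1}},
    "G_elongatus": {"a": {"1": 1, "2": 1, "3": 1}},
    "G_conglobatus": {"a": {"1": 1, "2": 1}, "b": {"1": 1}},
    "G_tenellus": {"a": {"1": 1, "2": 1}},
}

#: morphospecies forming the ingroup (the outgroup G. rubescens is
#: excluded from genotype counts, as in the published survey)
STUDY_INGROUP = (
    "G_ruber_albus", "G_ruber_ruber", "G_elongatus", "G_conglobatus",
    "G_tenellus",
)
STUDY_RUBER_PLEXUS = ("G_ruber_albus", "G_ruber_ruber", "G_elongatus")


def _study_support_allocation() -> dict[str, int]:
    """Direct-read support per singleton basetype, summing with the
    cloned reads to the 147 curated sequences of the survey design."""
    # 14 singleton basetypes; 12 cloned rubescens reads + 3 ruber clones
    # leave 132 direct reads to distribute (147 total curated)
    counts = [24, 20, 16, 12, 10, 9, 8, 7, 6, 5, 5, 4, 3, 3]
    assert sum(counts) == 132
    return counts


def study_barcode_dataset(seed: int = 0, partial_reads: int = 40,
                          seq_length: int = 1000):
    """Synthetic barcode survey with the published design planted.

    Plants 17 basetypes in 15 basegroups across 6 morphospecies: the
    *G. rubescens* basegroup holds three co-occurring copy variants
    witnessed by two cloned individuals, one *G. ruber albus* individual
    carries a single-individual co-occurrence (the contamination case the
    survey rejected), and the 147 curated reads are complemented by
    ``partial_reads`` truncated low-quality reads.  Returns
    ``(records, stations, truth)`` like :func:`generate_barcode_dataset`.
    """
    rng = np.random.default_rng(seed)
    stations = _station_table(rng, 40)
    root = _random_seq(rng, seq_length)

    plan = []
    indiv_counter = 0

    def next_ind():
        nonlocal indiv_counter
        indiv_counter += 1
        return f"IND{indiv_counter:04d}"

    support = iter(_study_support_allocation())
    motifs = {}  # basetype full name -> motif
    for morpho, genotypes in _STUDY_TAXONOMY.items():
        ms_seq = _mutate(rng, root, 0.08)
        for geno, basegroups in genotypes.items():
            gt_seq = _mutate(rng, ms_seq, 0.02)
            gt_name = f"{morpho}/{geno}"
            for bg, n_bt in basegroups.items():
                bg_seq = _mutate(rng, gt_seq, 0.002)
                bg_name = f"{gt_name}/{bg}"
                if n_bt == 1:
                    bt_name = f"{bg_name}/bt1"
                    motifs[bt_name] = bg_seq
                    n_reads = next(support)
                    for _ in range(n_reads):
                        plan.append((morpho, gt_name, bg_name, bt_name,
                                     bg_seq, next_ind(), 1, "direct"))
                else:
                    # co-occurring copy variants cloned from 2 individuals,
                    # 2 clones per variant per individual -> support 4 each;
                    # one substitution at a distinct site per variant keeps
                    # the motifs distinct for every seed
                    variants = [bg_seq]
                    var_pos = rng.choice(seq_length, size=n_bt - 1,
                                         replace=False)
                    for p in var_pos:
                        v = bg_seq.copy()
                        v[p] = rng.choice(NUCLEOTIDES[NUCLEOTIDES != v[p]])
                        variants.append(v)
                    for _ in range(2):
                        ind = next_ind()
                        for vi, vseq in enumerate(variants):
                            plan.append((morpho, gt_name, bg_name,
                                         f"{bg_name}/bt{vi + 1}", vseq,
                                         ind, 2, "clone"))
                    for vi, vseq in enumerate(variants):
                        motifs[f"{bg_name}/bt{vi + 1}"] = vseq

    # single-individual co-occurrence: three clones from one G. ruber
    # albus individual carrying the a/1 motif twice and the a/2 motif once
    ind = next_ind()
    plan.append(("G_ruber_albus", "G_ruber_albus/a", "G_ruber_albus/a/1",
                 "G_ruber_albus/a/1/bt1", motifs["G_ruber_albus/a/1/bt1"],
                 ind, 2, "clone"))
    plan.append(("G_ruber_albus", "G_ruber_albus/a", "G_ruber_albus/a/2",
                 "G_ruber_albus/a/2/bt1", motifs["G_ruber_albus/a/2/bt1"],
                 ind, 1, "clone"))

    records, truth = _emit_records(plan, stations, rng, 0.0, seq_length)

    # partial low-quality reads: truncated copies of existing motifs
    if partial_reads:
        motif_items = list(motifs.items())
        extra_plan = []
        for _ in range(partial_reads):
            bt_name, motif = motif_items[rng.integers(0, len(motif_items))]
            parts = bt_name.split("/")
            extra_plan.append((parts[0], f"{parts[0]}/{parts[1]}",
                               "/".join(parts[:3]), bt_name, motif,
                               next_ind(), 1, "direct"))
        extra, extra_truth = _emit_records(
            extra_plan, stations, rng, 1.0, seq_length, id_start=len(records)
        )
        records = pd.concat([records, extra], ignore_index=True)
        truth = pd.concat([truth, extra_truth], ignore_index=True)

    return records, stations, truth
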