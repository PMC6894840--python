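"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes the stages in dependency order — simulate (or
load), curate, delimit, richness, ecology, ontogeny — under one
declarative configuration, writing every intermediate table plus a
provenance manifest (config hash, seed, package version) into the run
directory.  Re-running with an identical configuration reproduces
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__, curation, delimitation, ecology, ontogeny, richness, synth
from .io import write_fasta, write_json, write_metadata, write_phylip

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "stages": {
        "simulate": True,
        "curate": True,
        "delimit": True,
        "richness": True,
        "ecology": True,
        "ontogeny": True,
    },
    "curation": {"min_replication": 3, "min_cooccurrence_individuals": 2},
    "abgd": {"Pmin": 0.001, "Pmax": 0.1, "n_steps": 10, "X": 1.5},
    "richness": {"level": "lvl3", "interval_convention": "half_width"},
    "ecology": {"level": "lvl2"},
    "synthetic": {"partial_reads": 40},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: dict | None = None, outdir=None) -> dict:
    """Run the configured stages; returns the in-memory results bundle.

    The run directory receives FASTA/TSV/CSV/JSON artefacts per stage
    and ``manifest.json`` recording configuration, hash, seed and
    package version.
    """
    config = _merge(DEFAULT_CONFIG, config or {})
    outdir = Path(outdir) if outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    stages = config["stages"]
    results: dict = {"config": config}

    def run_stage(name, fn):
        if not stages.get(name, False):
            return
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - named re-raise
            raise StageError(name, exc) from exc

    # ------------------------------------------------------------ simulate
    def _simulate():
        records, stations, truth = synth.study_barcode_dataset(
            seed=seed,
            partial_reads=int(config["synthetic"]["partial_reads"]),
        )
        env = synth.generate_environment_table(stations, seed=seed + 1)
        results.update(records=records, stations=stations, truth=truth,
                       environment=env)
        if outdir:
            write_fasta(
                dict(zip(records["sequence_id"], records["sequence"])),
                outdir / "sequences.fasta",
            )
            write_metadata(records.drop(columns=["sequence"]),
                           outdir / "metadata.tsv")
            write_metadata(truth, outdir / "truth.tsv")
            env.to_csv(outdir / "environment.csv", index=False)

    # -------------------------------------------------------------- curate
    def _curate():
        recs = curation.records_from_frame(results["records"])
        curated, attribution_queue = curation.filter_replicated(
            recs, config["curation"]["min_replication"]
        )
        basetypes = curation.extract_basetypes(curated)
        basegroups, rejected = curation.assemble_basegroups(
            basetypes, curated,
            config["curation"]["min_cooccurrence_individuals"],
        )
        results.update(curated=curated, attribution_queue=attribution_queue,
                       basetypes=basetypes, basegroups=basegroups,
                       rejected_cooccurrences=rejected)
        if outdir:
            pd.DataFrame(
                [{"basetype_id": bt.basetype_id, "support": bt.support,
                  "motif": bt.motif} for bt in basetypes]
            ).to_csv(outdir / "basetypes.tsv", sep="\t", index=False)
            pd.DataFrame(
                [{"basegroup_id": bg.basegroup_id,
                  "basetypes": ",".join(bg.basetypes)} for bg in basegroups]
            ).to_csv(outdir / "basegroups.tsv", sep="\t", index=False)
            write_json(rejected, outdir / "rejected_cooccurrences.json")

    # ------------------------------------------------------------- delimit
    def _delimit():
        basetypes = results["basetypes"]
        alignment = {bt.basetype_id: bt.motif for bt in basetypes}
        dm = delimitation.k80_distance(alignment)
        cfg = delimitation.AbgdConfig(**config["abgd"])
        _, initial, recursive = delimitation.abgd_partition(dm, cfg)
        morpho = _morphospecies_of_basetypes(
            basetypes, results["curated"]
        )
        hierarchy = delimitation.build_hierarchy(
            [initial, recursive], results["basegroups"], morpho
        )
        labels = {
            level: hierarchy.assignments[level].to_dict()
            for level in ("lvl1", "lvl2", "lvl3")
        }
        diag = curation.compute_diagnostic_sites(alignment, labels)
        attributions = [
            curation.attribute_partial(r, diag, alignment, labels)
            for r in results["attribution_queue"]
        ]
        results.update(distance=dm, partition_initial=initial,
                       partition_recursive=recursive, hierarchy=hierarchy,
                       diagnostic_sites=diag, attributions=attributions)
        if outdir:
            write_phylip(dm, outdir / "distances.phy")
            hierarchy.assignments.to_csv(outdir / "hierarchy.tsv", sep="\t")
            write_json(hierarchy.validation, outdir / "validation.json")
            pd.DataFrame(
                [{"sequence_id": a["sequence_id"], "level": a["level"],
                  "label": a["label"],
                  "evidence_sites": len(a["evidence"])}
                 for a in attributions]
            ).to_csv(outdir / "attributions.tsv", sep="\t", index=False)

    # ------------------------------------------------------------ richness
    def _richness():
        occ = _occurrence_table(results)
        level = config["richness"]["level"]
        inc = richness.build_incidence(occ, taxon_col=level)
        est = richness.jackknife1(inc)
        covered = richness.coverage_test(
            est, config["richness"]["interval_convention"]
        )
        curve = richness.rarefaction(inc, mode="analytic")
        results.update(incidence=inc, jackknife=est, coverage=covered,
                       rarefaction=curve)
        if outdir:
            table = pd.DataFrame(
                [{"level": level, "S_o": est.S_o, "S_e": est.S_e,
                  "CI_95": est.CI_95, "n_samples": est.n,
                  "S_o_in_interval": covered}]
            )
            table.to_csv(outdir / "richness.tsv", sep="\t", index=False)
            curve.to_csv(outdir / "rarefaction.csv", index=False)

    # ------------------------------------------------------------- ecology
    def _ecology():
        occ = _occurrence_table(results)
        env = ecology.attach_environment(
            occ.rename(columns={"taxon": "ignore"}), results["environment"]
        )
        level = config["ecology"]["level"]
        merged = occ.merge(env, on="sequence_id")
        merged["taxon"] = merged[level]
        tests = ecology.niche_comparison(merged)
        months = [
            ecology.month_normalize(d, lat)
            for d, lat in zip(occ["date"], occ["latitude"])
        ]
        windrose = (
            pd.DataFrame({"taxon": occ[level], "month": months})
            .value_counts().rename("count").reset_index()
            .sort_values(["taxon", "month"]).reset_index(drop=True)
        )
        results.update(environment_attached=merged, niche_tests=tests,
                       windrose=windrose)
        if outdir:
            tests.to_csv(outdir / "niche_tests.tsv", sep="\t", index=False)
            windrose.to_csv(outdir / "windrose.csv", index=False)

    # ------------------------------------------------------------ ontogeny
    def _ontogeny():
        shells = {}
        for species, cfg in synth.study_shell_configs(seed).items():
            frame = synth.generate_shell(cfg)
            series = ontogeny.ChamberSeries.from_frame(frame, species)
            axis = ontogeny.estimate_axis(series, method="fitted")
            traj = ontogeny.raup_parameters(series, axis)
            alloc = ontogeny.volume_allocation(series)
            kummer, ratio = ontogeny.detect_kummerform(series)
            stages_lbl = ontogeny.annotate_stages(series, traj)
            shells[species] = {
                "series": series, "trajectory": traj, "allocation": alloc,
                "kummerform": kummer, "kummerform_ratio": ratio,
                "stages": stages_lbl,
            }
            if outdir:
                traj.to_csv(outdir / f"trajectory_{species}.csv", index=False)
        results["shells"] = shells
        if outdir:
            summary = pd.DataFrame(
                [{"specimen": sp, "n_chambers": len(d["series"].data),
                  "last3_pct": d["allocation"]["last3_pct"],
                  "kummerform": d["kummerform"],
                  "proloculus_gt_deuteroconch":
                      d["series"].volumes[0] > d["series"].volumes[1]}
                 for sp, d in shells.items()]
            )
            summary.to_csv(outdir / "ontogeny_summary.tsv", sep="\t",
                           index=False)

    run_stage("simulate", _simulate)
    run_stage("curate", _curate)
    run_stage("delimit", _delimit)
    run_stage("richness", _richness)
    run_stage("ecology", _ecology)
    run_stage("ontogeny", _ontogeny)

    manifest = {
        "config": config,
        "config_hash": _config_hash(config),
        "seed": seed,
        "version": __version__,
        "stages_run": [s for s, on in stages.items() if on],
    }
    results["manifest"] = manifest
    if outdir:
        write_json(manifest, outdir / "manifest.json")
    return results


def _morphospecies_of_basetypes(basetypes, curated) -> dict[str, str]:
    """Majority morphospecies label of each basetype's member reads."""
    by_id = {r.sequence_id: r for r in curated}
    out = {}
    for bt in basetypes:
        labels = pd.Series(
            [by_id[s].morphospecies for s in bt.members if s in by_id]
        )
        out[bt.basetype_id] = labels.mode().iloc[0]
    return out


def _occurrence_table(results) -> pd.DataFrame:
    """Long table of curated reads with their MOTU labels and metadata."""
    hierarchy = results["hierarchy"].assignments
    basetype_of_motif = {
        bt.motif: bt.basetype_id for bt in results["basetypes"]
    }
    rows = []
    for r in results["curated"]:
        bt = basetype_of_motif[r.motif]
        rows.append({
            "sequence_id": r.sequence_id,
            "station_id": r.station_id,
            "date": r.date,
            "latitude": r.latitude,
            "longitude": r.longitude,
            "morphospecies": r.morphospecies,
            "basetype_id": bt,
            "lvl1": hierarchy.loc[bt, "lvl1"],
            "lvl2": hierarchy.loc[bt, "lvl2"],
            "lvl3": hierarchy.loc[bt, "lvl3"],
        })
    return pd.DataFrame(rows)
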