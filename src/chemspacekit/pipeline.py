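"""End-to-end pipeline: curate -> profile -> scaffolds -> diversity ->
cluster/MCS -> NPL -> multiverse, driven by a YAML config.

A run produces per-library report files (CSV/JSON) and a run manifest with
the config snapshot, fanned-out stage seeds, per-output SHA-256 hashes and
timing — enough to re-run the deterministic stages bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clustering import ClusterParams, cluster_and_consolidate, mcs_table, mw_filter
from .curation import CompoundLibrary, compound_overlap, read_library
from .descriptors import descriptor_table
from .diversity import compare_libraries, pairwise_distribution
from .fingerprints import fingerprint_library
from .multiverse import EmbeddingConfig, build_multiverse
from .npl import train_npl
from .scaffolds import csr_curve, scaffold_index, scaled_shannon_entropy
from .synthetic import gen_npl_corpora

log = logging.getLogger("chemspacekit")

ALL_STAGES = (
    "curate",
    "descriptors",
    "scaffolds",
    "diversity",
    "cluster",
    "npl",
    "multiverse",
)

# fixed fan-out offsets from the master seed, echoed in the manifest
SEED_OFFSETS = {"diversity": 11, "npl": 23, "multiverse": 37, "fingerprints": 53}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Run the configured stages over the configured libraries.

    ``config`` is a YAML path or an equivalent dict with keys:
    ``libraries`` (name -> {path, format, smiles_column}), ``stages`` (subset
    of curate/descriptors/scaffolds/diversity/cluster/npl/multiverse),
    ``seed``, ``keep_chirality``, ``representations``, ``output_dir`` and
    optional per-stage parameter blocks. Returns the manifest dict.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    stages = list(config.get("stages", ALL_STAGES))
    lib_specs = config.get("libraries", {})
    if not lib_specs or not stages:
        raise ValueError("config must name at least one library and one stage")
    outdir = Path(outdir or config.get("output_dir", "chemspace_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    master_seed = int(config.get("seed", 0))
    keep_chirality = bool(config.get("keep_chirality", True))
    representations = list(
        config.get("representations", ["keys166", "circular4-1024", "map4-2048"])
    )

    manifest: dict = {
        "tool_version": __version__,
        "config": config,
        "seeds": {"master": master_seed}
        | {k: master_seed + v for k, v in SEED_OFFSETS.items()},
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, path: Path):
        manifest["outputs"][str(path.relative_to(outdir))] = _sha256(path)

    def run_stage(stage: str, fn):
        t0 = time.time()
        log.info("stage %s started", stage)
        fn()
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        log.info("stage %s done in %.1fs", stage, time.time() - t0)

    # --- curate (always required as input to everything else)
    libraries: dict[str, CompoundLibrary] = {}

    def do_curate():
        for name, spec in lib_specs.items():
            lib = read_library(
                spec["path"],
                format=spec.get("format"),
                smiles_column=spec.get("smiles_column"),
                name=name,
                keep_chirality=keep_chirality,
            )
            libraries[name] = lib
            out = outdir / f"{name}_curated.csv"
            lib.write_csv(out)
            record("curate", out)
            rep = outdir / f"{name}_curation_report.json"
            lib.write_curation_report(rep)
            record("curate", rep)
        if len(libraries) >= 2:
            report = compound_overlap(list(libraries.values()), use_chirality=False)
            out = outdir / "compound_overlap.json"
            with open(out, "w") as fh:
                json.dump(
                    {
                        "libraries": report.library_names,
                        "regions": {"+".join(k): v for k, v in report.regions.items()},
                    },
                    fh,
                    indent=2,
                )
            record("curate", out)

    run_stage("curate", do_curate)

    summary_rows = {
        name: {"library": name, "size_curated": len(lib)}
        for name, lib in libraries.items()
    }

    if "descriptors" in stages:

        def do_descriptors():
            for name, lib in libraries.items():
                table = descriptor_table(
                    lib,
                    complexity_max_atoms=int(config.get("complexity_max_atoms", 7)),
                    compute_complexity=bool(config.get("compute_complexity", True)),
                )
                out = outdir / f"{name}_descriptors.csv"
                table.write_csv(out)
                record("descriptors", out)
                sj = outdir / f"{name}_descriptor_summary.json"
                table.write_summary_json(sj)
                record("descriptors", sj)
                summary_rows[name]["mean_csp3"] = float(table.records["csp3"].mean())

        run_stage("descriptors", do_descriptors)

    if "scaffolds" in stages:

        def do_scaffolds():
            for name, lib in libraries.items():
                index = scaffold_index(lib)
                out = outdir / f"{name}_scaffolds.csv"
                index.write_csv(out)
                record("scaffolds", out)
                summary_rows[name]["acyclic_fraction"] = index.acyclic_fraction
                summary_rows[name]["n_scaffolds"] = len(index.scaffold_to_ids)
                if index.counts:
                    curve = csr_curve(index)
                    cf = outdir / f"{name}_csr.csv"
                    curve.to_frame().to_csv(cf, index=False)
                    record("scaffolds", cf)
                    summary_rows[name]["csr_auc"] = curve.auc
                if len(index.counts) >= 2:
                    sse = scaled_shannon_entropy(index, top_n=15)
                    summary_rows[name]["sse_top15"] = sse.sse

        run_stage("scaffolds", do_scaffolds)

    if "diversity" in stages:

        def do_diversity():
            seed = manifest["seeds"]["diversity"]
            for rep in representations:
                dists = []
                for name, lib in libraries.items():
                    fps = fingerprint_library(
                        lib, rep, seed=manifest["seeds"]["fingerprints"]
                    )
                    dist = pairwise_distribution(
                        fps,
                        sample_size=int(config.get("sample_size", 1000)),
                        n_samples=int(config.get("n_samples", 5)),
                        seed=seed,
                    )
                    dists.append(dist)
                    summary_rows[name][f"mean_sim_{rep}"] = dist.mean
                    summary_rows[name][f"median_sim_{rep}"] = dist.median
                ranking = compare_libraries(dists)
                out = outdir / f"diversity_{rep}.csv"
                ranking.to_csv(out)
                record("diversity", out)

        run_stage("diversity", do_diversity)

    if "cluster" in stages:

        def do_cluster():
            params = ClusterParams(
                dissimilarity_cutoff=float(config.get("dissimilarity_cutoff", 0.05)),
                mw_cap=float(config.get("mw_cap", 1000.0)),
                representation=config.get("cluster_representation", "circular4-1024"),
            )
            for name, lib in libraries.items():
                filtered = mw_filter(lib, params.mw_cap)
                if len(filtered) < 2:
                    log.warning("library %s too small after MW filter; skipped", name)
                    continue
                fps = fingerprint_library(
                    filtered, params.representation, seed=manifest["seeds"]["fingerprints"]
                )
                assignment, mcs_results = cluster_and_consolidate(filtered, fps, params)
                out = outdir / f"{name}_clusters.csv"
                assignment.to_frame().to_csv(out, index=False)
                record("cluster", out)
                mt = outdir / f"{name}_mcs.csv"
                mcs_table(mcs_results).to_csv(mt, index=False)
                record("cluster", mt)
                summary_rows[name]["n_clusters"] = len(assignment.clusters)
                summary_rows[name]["n_singletons"] = len(assignment.singletons)

        run_stage("cluster", do_cluster)

    if "npl" in stages:

        def do_npl():
            seed = manifest["seeds"]["npl"]
            n_train = int(config.get("npl_train_size", 100))
            np_lib, syn_lib = gen_npl_corpora(n_train, n_train, seed=seed)
            model = train_npl(np_lib, syn_lib)
            mp = outdir / "npl_model.json"
            model.to_json(mp)
            record("npl", mp)
            for name, lib in libraries.items():
                scores = model.score_samples(list(lib.molecules.values()))
                out = outdir / f"{name}_npl.csv"
                pd.DataFrame(
                    {"id": list(lib.molecules), "npl": scores}
                ).to_csv(out, index=False)
                record("npl", out)
                summary_rows[name]["mean_npl"] = float(scores.mean())

        run_stage("npl", do_npl)

    if "multiverse" in stages and len(libraries) >= 1:

        def do_multiverse():
            n_pool = sum(len(lib) for lib in libraries.values())
            perplexity = min(float(config.get("perplexity", 30.0)), (n_pool - 1) / 3.5)
            view = build_multiverse(
                list(libraries.values()),
                representations,
                EmbeddingConfig(
                    perplexity=perplexity, seed=manifest["seeds"]["multiverse"]
                ),
            )
            out = outdir / "multiverse_coordinates.csv"
            view.write_csv(out)
            record("multiverse", out)

        run_stage("multiverse", do_multiverse)

    summary = pd.DataFrame(list(summary_rows.values()))
    summary_path = outdir / "library_summary.csv"
    summary.to_csv(summary_path, index=False)
    record("summary", summary_path)

    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
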