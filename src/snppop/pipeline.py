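"""End-to-end orchestration: QC -> diversity -> LD/Ne -> ROH -> structure ->
admixture -> selection scan, driven by one config with one global seed.

Each stage writes its tables under the output directory and records counts,
timings and file names in a JSON run manifest.  Per-stage seeds derive from
the global seed by a fixed offset so a single integer reproduces every
stochastic step.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import admixture as admix
from . import diversity, io, ldne, qc, roh, scan, structure
from .dataset import GenotypeDataset

STAGE_SEED_OFFSETS = {
    "admixture": 11,
    "scan": 23,
    "fst_permutations": 37,
}


@dataclass
class RunConfig:
    ped: str | None = None
    map: str | None = None
    merge_ped: str | None = None
    merge_map: str | None = None
    out_dir: str = "snppop_out"
    seed: int = 0
    qc: qc.QCConfig = field(default_factory=qc.QCConfig)
    roh: roh.ROHConfig = field(default_factory=roh.ROHConfig)
    ld_max_distance_bp: int = 1_000_000
    ld_bin_width_bp: int = 50_000
    ne_generations: int = 50
    ne_alpha: float = 1.0
    admixture_k: list = field(default_factory=lambda: [2, 3, 4, 5])
    admixture_restarts: int = 5
    scan_K: int = 3
    scan_alpha: float = 0.05
    fst_flag_threshold: float = 0.5
    window_flank_bp: int = 500_000
    n_fst_permutations: int = 200
    stages: list = field(
        default_factory=lambda: [
            "qc",
            "diversity",
            "ld_ne",
            "roh",
            "structure",
            "admixture",
            "scan",
        ]
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        qc_cfg = qc.QCConfig(**raw.pop("qc", {}))
        roh_cfg = roh.ROHConfig(**raw.pop("roh", {}))
        return cls(qc=qc_cfg, roh=roh_cfg, **raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig, data: GenotypeDataset | None = None) -> dict:
    """Run the configured stages and return the manifest (also written as JSON).

    ``data`` may be passed directly (e.g. a simulated dataset); otherwise the
    PED/MAP paths in the config are read, and merged with the optional second
    dataset.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stages": {},
        "inputs": {},
        "outputs": [],
    }

    def emit(name: str, frame) -> None:
        path = out / name
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
        manifest["outputs"].append(name)

    try:
        if data is None:
            if not config.ped or not config.map:
                raise ValueError("config must provide ped/map paths or a dataset")
            data = io.read_ped_map(config.ped, config.map)
            manifest["inputs"]["ped"] = _hash_file(Path(config.ped))
            manifest["inputs"]["map"] = _hash_file(Path(config.map))
            if config.merge_ped:
                other = io.read_ped_map(config.merge_ped, config.merge_map)
                data, merge_report = io.merge_datasets(data, other)
                manifest["merge"] = asdict(merge_report)
    except Exception as e:  # noqa: BLE001
        _write_manifest(out, manifest)
        raise StageError("input", e) from e

    state: dict = {"raw": data}
    for stage in config.stages:
        t0 = time.perf_counter()
        try:
            _run_stage(stage, state, config, emit)
        except Exception as e:  # noqa: BLE001
            manifest["stages"][stage] = {"status": "failed", "error": str(e)}
            _write_manifest(out, manifest)
            raise StageError(stage, e) from e
        manifest["stages"][stage] = {
            "status": "completed",
            "seconds": round(time.perf_counter() - t0, 3),
            **state.get(f"{stage}_counts", {}),
        }
    for stage in ("qc", "diversity", "ld_ne", "roh", "structure", "admixture", "scan"):
        if stage not in config.stages:
            manifest["stages"].setdefault(stage, {"status": "skipped"})
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _run_stage(stage: str, state: dict, config: RunConfig, emit) -> None:
    data = state["raw"]
    if stage == "qc":
        filtered, r1 = qc.filter_call_rate(data, config.qc)
        maffed, r2 = qc.filter_maf(filtered, config.qc.maf_min)
        pruned, r3 = qc.ld_prune(maffed, config.qc)
        state["callrate_filtered"] = filtered  # ROH consumes this (no MAF filter)
        state["maf_filtered"] = maffed
        state["pruned"] = pruned
        state["qc_counts"] = {
            "variants_in": data.n_variants,
            "variants_after_call_rate": filtered.n_variants,
            "samples_after_call_rate": filtered.n_samples,
            "variants_after_maf": maffed.n_variants,
            "variants_after_prune": pruned.n_variants,
        }
    elif stage == "diversity":
        d = state.get("pruned", data)
        emit("diversity_summary.tsv", diversity.summary_table(d))
        table, mean_fst = diversity.per_marker_fst(state.get("maf_filtered", data))
        emit("per_marker_fst.tsv", table)
        state["per_marker_fst"] = table
        state["diversity_counts"] = {"mean_fst": mean_fst}
    elif stage == "ld_ne":
        d = state.get("callrate_filtered", data)
        rows = []
        for pop in d.populations:
            sub = d.subset_population(pop)
            curve = ldne.ld_decay(sub, config.ld_max_distance_bp, config.ld_bin_width_bp, None)
            curve.bins.insert(0, "population", pop)
            rows.append(curve.bins)
            pairs = ldne.ld_pairs(sub, config.ld_max_distance_bp)
            traj = ldne.ne_from_ld(
                pairs,
                generations=range(1, config.ne_generations + 1),
                alpha=config.ne_alpha,
                sample_n=sub.n_samples,
            )
            traj.points.insert(0, "population", pop)
            emit(f"ne_trajectory_{pop}.tsv", traj.points)
        import pandas as pd

        emit("ld_decay.tsv", pd.concat(rows, ignore_index=True))
    elif stage == "roh":
        d = state.get("callrate_filtered", data)
        segments = roh.detect_roh(d, config.roh)
        summaries = roh.froh(segments, d.samples["sample_id"])
        emit("roh_segments.tsv", roh.segments_table(segments))
        emit("froh.tsv", roh.froh_table(summaries))
        state["roh_counts"] = {"n_segments": len(segments)}
    elif stage == "structure":
        import pandas as pd

        d = state.get("pruned", data)
        res = structure.pca(d, n_components=10)
        evec = pd.DataFrame(
            res.eigenvectors, columns=[f"PC{i + 1}" for i in range(res.eigenvectors.shape[1])]
        )
        evec.insert(0, "sample_id", res.sample_ids)
        emit("pca_eigenvectors.tsv", evec)
        state["pca"] = res
        ibs = structure.ibs_matrix(d)
        emit(
            "nearest_neighbors.tsv",
            structure.nearest_neighbors(ibs, list(d.samples["sample_id"]), k=5),
        )
        # pairwise differentiation and distances use the dense (unpruned)
        # panel: pruning removes correlated differentiated markers and
        # attenuates F_ST
        dense = state.get("maf_filtered", data)
        if len(d.populations) >= 2:
            pw = structure.pairwise_fst(
                dense,
                n_permutations=config.n_fst_permutations,
                seed=config.seed + STAGE_SEED_OFFSETS["fst_permutations"],
            )
            mat = pd.DataFrame(pw.fst, index=pw.populations, columns=pw.populations)
            emit("pairwise_fst.tsv", mat.reset_index(names="population"))
            nm = pd.DataFrame(pw.nm, index=pw.populations, columns=pw.populations)
            emit("nm.tsv", nm.reset_index(names="population"))
            nei = structure.nei_distance(dense)
            emit(
                "nei_distance.tsv",
                pd.DataFrame(nei.nei_d, index=nei.labels, columns=nei.labels).reset_index(
                    names="population"
                ),
            )
            if len(d.populations) >= 3:
                newick = structure.nj_tree(nei.nei_d, nei.labels)
                (Path(config.out_dir) / "nj_tree.nwk").write_text(newick + "\n")
        state["structure_counts"] = {
            "pc1_pct": float(res.pct_variance[0]) if len(res.pct_variance) else None
        }
    elif stage == "admixture":
        import pandas as pd

        d = state.get("pruned", data)
        rows = []
        best = None
        for k in config.admixture_k:
            fit = admix.fit_admixture(
                d,
                k,
                seed=config.seed + STAGE_SEED_OFFSETS["admixture"],
                n_restarts=config.admixture_restarts,
            )
            fit.cv_error = admix.cv_error(
                d, k, seed=config.seed + STAGE_SEED_OFFSETS["admixture"]
            )
            rows.append({"k": k, "loglik": fit.loglik, "cv_error": fit.cv_error})
            if best is None or fit.cv_error < best.cv_error:
                best = fit
        emit("admixture_cv.tsv", pd.DataFrame(rows))
        q = pd.DataFrame(best.q, columns=[f"Q{i + 1}" for i in range(best.k)])
        q.insert(0, "sample_id", list(d.samples["sample_id"]))
        q.insert(1, "population", list(d.samples["population"]))
        emit("admixture_q.tsv", q)
        state["admixture_counts"] = {"best_k": best.k}
    elif stage == "scan":
        d = state.get("maf_filtered", data)
        pca_scores = state["pca"].eigenvectors if "pca" in state else None
        K = min(config.scan_K, d.n_samples - 1)
        result = scan.pcadapt_scan(d, K=K, alpha=config.scan_alpha, scores=pca_scores)
        table = result.table
        if "per_marker_fst" in state:
            fst = state["per_marker_fst"]["fst"].to_numpy()
            table = table.assign(
                fst=fst, flagged_fst=scan.fst_flags(state["per_marker_fst"], config.fst_flag_threshold)
            )
            flags = table["flagged_pcadapt"].to_numpy() | table["flagged_fst"].to_numpy()
        else:
            flags = table["flagged_pcadapt"].to_numpy()
        emit("selection_scan.tsv", table)
        windows = scan.candidate_windows(d.variants, flags, config.window_flank_bp)
        scan.write_bed(windows, Path(config.out_dir) / "candidate_windows.bed")
        state["scan_counts"] = {
            "lambda_gc": result.lambda_gc,
            "n_flagged": int(flags.sum()),
            "n_windows": len(windows),
        }
    else:
        raise ValueError(f"unknown stage '{stage}'")
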