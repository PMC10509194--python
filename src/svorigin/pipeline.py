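"""End-to-end orchestration of the synthetic-cohort analysis.

``run_pipeline`` executes the stages in dependency order — simulate ->
variant I/O -> divergence scan -> introgression classification ->
domestication contrast, with copy-number genotyping and pangenome
statistics as independent side stages — and writes a machine-readable
manifest (stage status, parameter echo, content digests of every output).

Every output file starts with a header comment carrying the tool version,
the configuration digest and the global seed, so a run can be identified
from any of its artifacts.  Per-stage seeds are derived from the global
seed by fixed documented offsets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from svorigin import cn as cn_mod
from svorigin import divergence, domestication, introgression, pangenome, synthetic
from svorigin import variant_io

__version__ = "0.1.0"

log = logging.getLogger("svorigin")

# Seed offsets per randomized stage (added to the global seed).
SEED_OFFSETS = {
    "cohort": 0,
    "events": 1,
    "inject": 2,
    "cn": 3,
    "pangenome": 4,
}


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    outdir: str = "results/pipeline"
    seed: int = 0
    cohort: synthetic.CohortConfig | None = None
    event_sv_fraction: float = 0.3
    classifier: introgression.ClassifierConfig = field(
        default_factory=introgression.ClassifierConfig
    )
    contrast: domestication.ContrastConfig = field(
        default_factory=domestication.ContrastConfig
    )
    roundtrip_io: bool = True
    stages: tuple = (
        "simulate",
        "divergence",
        "introgression",
        "domestication",
        "cn",
        "pangenome",
    )

    def resolved_cohort(self) -> synthetic.CohortConfig:
        if self.cohort is not None:
            return self.cohort
        return synthetic.CohortConfig(seed=self.seed + SEED_OFFSETS["cohort"])


def _config_digest(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    payload = dataclasses.asdict(config)
    payload.pop("outdir", None)  # a location, not a parameter
    blob = json.dumps(payload, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _file_digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, meta: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {meta}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; return (and write) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest = _config_digest(config)
    meta = f"svorigin={__version__} config={digest} seed={config.seed}"
    stages = list(config.stages)
    if "domestication" in stages and "introgression" not in stages:
        raise PipelineError(
            "stage 'domestication' requires stage 'introgression': "
            "origin calls required for introgression exclusion"
        )
    manifest = {
        "tool": "svorigin",
        "version": __version__,
        "seed": config.seed,
        "config_digest": digest,
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, outputs: dict, t0: float) -> None:
        manifest["stages"][stage] = {
            "status": "ok",
            "seconds": round(time.time() - t0, 3),
        }
        for name, path in outputs.items():
            manifest["outputs"][name] = {
                "path": str(path),
                "sha256": _file_digest(Path(path)),
            }

    cohort = truth = None
    snp_matrix = sv_matrix = popmap = None
    sv_calls = None

    if "simulate" in stages:
        t0 = time.time()
        log.info("simulate: generating cohort")
        cohort_cfg = config.resolved_cohort()
        cohort = synthetic.simulate_cohort(cohort_cfg)
        events = synthetic.random_cattle_to_yak_events(
            cohort,
            sv_fraction=config.event_sv_fraction,
            seed=config.seed + SEED_OFFSETS["events"],
        )
        cohort, truth = synthetic.inject_introgression(
            cohort, events, seed=config.seed + SEED_OFFSETS["inject"]
        )
        snp_matrix, sv_matrix = synthetic.cohort_to_matrices(cohort)
        popmap = dict(cohort.populations)

        snp_path = outdir / "snps.vcf"
        sv_path = outdir / "svs.vcf"
        variant_io.write_vcf(snp_matrix, snp_path, header_comment=meta)
        variant_io.write_vcf(sv_matrix, sv_path, header_comment=meta)
        pop_path = outdir / "popmap.tsv"
        with open(pop_path, "w") as fh:
            fh.write(f"# {meta}\n")
            for s, p in popmap.items():
                fh.write(f"{s}\t{p}\n")
        truth_path = outdir / "truth.tsv"
        _write_tsv(truth, truth_path, meta)
        if config.roundtrip_io:
            snp_matrix = variant_io.read_phased_vcf(snp_path, require_phase=True)
            sv_matrix = variant_io.read_phased_vcf(sv_path, require_phase=True)
        record(
            "simulate",
            {"snps": snp_path, "svs": sv_path, "popmap": pop_path, "truth": truth_path},
            t0,
        )
    elif set(stages) & {"divergence", "introgression", "domestication"}:
        raise PipelineError("analysis stages require stage 'simulate' (missing input)")

    if "divergence" in stages:
        t0 = time.time()
        log.info("divergence: Weir-Cockerham theta and Phi_ST per SV")
        gt_wild = divergence.group_genotypes(sv_matrix, popmap, "wild_yak")
        gt_cattle = divergence.group_genotypes(sv_matrix, popmap, "cattle")
        theta = divergence.fst_weir_cockerham(gt_wild, gt_cattle)
        phist = divergence.phi_st(gt_wild, gt_cattle)
        r, p = divergence.fst_phist_concordance(theta, phist)
        fixed = divergence.outlier_scan(theta, 1.0, mode="equals")
        stats_df = sv_matrix.variants[["chrom", "pos", "id"]].copy()
        stats_df["theta_fst"] = theta
        stats_df["phi_st"] = phist
        stats_df["fst_fixed_outlier"] = np.isin(
            np.arange(len(stats_df)), fixed
        )
        path = outdir / "sv_divergence.tsv"
        _write_tsv(stats_df, path, f"{meta} pearson_r={r:.4f} p={p:.3g}")
        record("divergence", {"sv_divergence": path}, t0)

    if "introgression" in stages:
        t0 = time.time()
        log.info("introgression: per-SV haplotype trees")
        panels = introgression.panels_from_cohort(cohort)
        sv_calls = [
            introgression.classify_panel(panel, config.classifier)
            for panel in panels
        ]
        frames = [c.calls_frame() for c in sv_calls]
        nonempty = [f for f in frames if len(f)]
        calls_df = pd.concat(nonempty or frames[:1], ignore_index=True)
        dir_df = pd.DataFrame(
            [(c.sv_id, c.direction, c.n_tag_snps, c.flag) for c in sv_calls],
            columns=["sv_id", "direction", "n_tag_snps", "flag"],
        )
        per_sample, fraction = introgression.cohort_introgression_summary(
            sv_calls, popmap
        )
        summary = pd.DataFrame(
            sorted(per_sample.items()), columns=["sample", "n_introgressed_svs"]
        )
        calls_path = outdir / "haplotype_origins.tsv"
        dir_path = outdir / "sv_directions.tsv"
        sum_path = outdir / "introgression_summary.tsv"
        _write_tsv(calls_df, calls_path, meta)
        _write_tsv(dir_df, dir_path, meta)
        _write_tsv(summary, sum_path, f"{meta} yak_carrier_fraction={fraction:.4f}")
        record(
            "introgression",
            {"haplotype_origins": calls_path, "sv_directions": dir_path,
             "introgression_summary": sum_path},
            t0,
        )

    if "domestication" in stages:
        t0 = time.time()
        log.info("domestication: wild-vs-domestic AF contrast")
        contrast = domestication.af_contrast_scan(sv_matrix, popmap, config.contrast)
        directions = {c.sv_id: c.direction for c in sv_calls}
        candidates = domestication.select_candidates(
            contrast, directions, config.contrast
        )
        c_path = outdir / "domestication_contrast.tsv"
        cand_path = outdir / "domestication_candidates.tsv"
        _write_tsv(contrast, c_path, meta)
        _write_tsv(candidates, cand_path, meta)
        record(
            "domestication",
            {"contrast": c_path, "candidates": cand_path},
            t0,
        )

    if "cn" in stages:
        t0 = time.time()
        log.info("cn: depth simulation and copy-number calls")
        rng = np.random.default_rng(config.seed + SEED_OFFSETS["cn"])
        segments = {"A": 6000, "BC": 9000, "DE": 7000, "alpha": 5000, "betagamma": 8000}
        n = 40
        true_cn = pd.DataFrame(
            rng.integers(0, 7, size=(n, len(segments))),
            index=[f"cnS{i + 1:03d}" for i in range(n)],
            columns=list(segments),
        )
        depths = synthetic.simulate_segment_depths(
            true_cn, segments, base_depth=20.0,
            seed=config.seed + SEED_OFFSETS["cn"],
        )
        calls = cn_mod.segment_copy_number(depths)
        path = outdir / "cn_calls.tsv"
        _write_tsv(calls, path, meta)
        acc = float(
            (calls.set_index(["sample", "segment"])["copy_number"]
             == true_cn.stack().rename_axis(["sample", "segment"])).mean()
        )
        manifest.setdefault("metrics", {})["cn_accuracy"] = acc
        record("cn", {"cn_calls": path}, t0)

    if "pangenome" in stages:
        t0 = time.time()
        log.info("pangenome: presence classes and saturation curves")
        fam = synthetic.simulate_family_matrix(
            n_genomes=22, n_families=2000,
            seed=config.seed + SEED_OFFSETS["pangenome"],
        )
        classes, fractions = pangenome.classify_presence(fam)
        curves = pangenome.saturation_curves(fam)
        absent = pangenome.pairwise_absence(fam)
        cls_path = outdir / "family_classes.tsv"
        curve_path = outdir / "saturation_curves.tsv"
        abs_path = outdir / "pairwise_absence.tsv"
        _write_tsv(
            classes.rename("presence_class").rename_axis("family").reset_index(),
            cls_path,
            f"{meta} fractions={json.dumps(fractions)}",
        )
        _write_tsv(curves, curve_path, meta)
        _write_tsv(absent.reset_index(names="genome"), abs_path, meta)
        record(
            "pangenome",
            {"family_classes": cls_path, "saturation_curves": curve_path,
             "pairwise_absence": abs_path},
            t0,
        )

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
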