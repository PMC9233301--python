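"""End-to-end orchestration: simulate/load -> QC -> paint -> cluster ->
profiles -> IBD -> Ne -> ROH/F.

Every randomized stage draws its seed from the single global seed through
``numpy.random.SeedSequence(seed, spawn_key=(stage,))``, so a rerun with the
same configuration is bit-identical.  Each stage writes its declared outputs
into the run directory and logs counts; errors abort with the stage name.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, community, demography, ibd, inbreeding, io, paint, profiles, simdata
from .paint import PaintConfig
from .inbreeding import ROHParams
from .io import QCParams

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # inputs: either a simulation config or paths to real data
    sim: simdata.SimConfig | None = None
    vcf: str | None = None
    map: str | None = None
    labels: str | None = None
    # stage parameters
    qc: QCParams = field(default_factory=QCParams)
    run_qc: bool = True
    paint: PaintConfig = field(default_factory=PaintConfig)
    edge_low: float = 2.0
    edge_high: float = 25.0
    leiden_depth: int = 4
    min_community: int = 100
    resolution: float = 1.0
    ibd_min_cm: float = 1.0
    merge_gap_cm: float = 0.6
    merge_max_discordant: int = 1
    ne_min_cm: float = 4.0
    ne_generations: int = 50
    bootstrap: int = 100
    ne_smoothing: float = 1.0
    ne_report_generations: tuple = (5, 15, 30)
    roh: ROHParams = field(default_factory=ROHParams)
    cluster_groups: dict | None = None  # leaf label -> F_SNP group; default: each leaf
    genome_bp: int | None = None  # default: simulated genome / map extent
    outdir: str = "hapshare_run"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.sim is None:
            if self.vcf is None or self.map is None:
                raise ValueError("need either a simulation config or vcf+map paths")
            for p in (self.vcf, self.map, self.labels):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = simdata.SimConfig(**raw["sim"])
        for key, sub in (("qc", QCParams), ("paint", PaintConfig), ("roh", ROHParams)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                logger.info("stage %s", name)
                return fn(*args, **kwargs)
            except Exception as err:
                raise RuntimeError(f"pipeline stage '{name}' failed: {err}") from err

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the artifact directory."""
    logging.basicConfig(level=config.log_level)
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "hapshare_version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    # ---- inputs ----------------------------------------------------------
    truth = None
    if config.sim is not None:
        sim = _stage("simulate")(simdata.simulate)(config.sim)
        panel, labels = sim.panel, sim.labels
        truth = sim.truth_ibd(min_cM=1.0)
        io.write_phased_vcf(panel, out / "panel.vcf")
        io.write_map(panel, out / "sites.map")
        labels.to_csv(out / "labels.tsv", sep="\t")
        truth.to_csv(out / "truth_ibd.tsv", sep="\t", index=False)
        chrom_lengths = [c.length_cM for c in config.sim.chromosomes]
        genome_bp = config.genome_bp or sum(c.length_bp for c in config.sim.chromosomes)
    else:
        panel = _stage("read inputs")(io.read_phased_vcf)(config.vcf, config.map)
        labels = (
            pd.read_csv(config.labels, sep="\t", index_col=0).iloc[:, 0]
            if config.labels
            else pd.Series("all", index=panel.individuals)
        )
        chrom_lengths = [
            float(panel.site_cM[panel.chrom_slice(c)].max() - panel.site_cM[panel.chrom_slice(c)].min())
            for c in panel.chromosomes()
        ]
        genome_bp = config.genome_bp or inbreeding.GENOME_BP
    manifest["stages"]["input"] = {"individuals": panel.n_ind, "sites": panel.n_sites}

    # ---- QC --------------------------------------------------------------
    if config.run_qc:
        panel, qc_report = _stage("qc")(io.qc_filter)(panel, config.qc)
        manifest["stages"]["qc"] = qc_report
        (out / "qc_report.json").write_text(json.dumps(qc_report, indent=2))

    # ---- painting --------------------------------------------------------
    pcfg = dataclasses.replace(config.paint, seed=int(np.random.SeedSequence(config.seed, spawn_key=(10,)).generate_state(1)[0] % (2**31)))
    coan = _stage("paint")(paint.paint_panel)(panel, pcfg)
    io.write_matrix_tsv(coan.chunkcounts, out / "chunkcounts.tsv")
    io.write_matrix_tsv(coan.chunklengths, out / "chunklengths.tsv")
    pcs = paint.coancestry_pca(coan, k=min(10, panel.n_ind - 1))
    pcs.to_csv(out / "coancestry_pca.tsv", sep="\t")
    manifest["stages"]["paint"] = {"total_map_cM": coan.total_map_length_cM}

    # ---- clustering ------------------------------------------------------
    graph = _stage("graph")(community.build_graph)(coan, config.edge_low, config.edge_high)
    tree = _stage("leiden")(community.leiden_recursive)(
        graph,
        max_depth=config.leiden_depth,
        min_size=config.min_community,
        resolution=config.resolution,
        seed=int(np.random.SeedSequence(config.seed, spawn_key=(11,)).generate_state(1)[0] % (2**31)),
    )
    assignment = tree.assignment().reindex(panel.individuals)
    pd.DataFrame({"individual": assignment.index, "cluster": assignment.values}).to_csv(
        out / "clusters.tsv", sep="\t", index=False
    )
    (out / "tree.nwk").write_text(tree.to_newick() + "\n")
    manifest["stages"]["leiden"] = {"n_leaves": len(tree.leaves())}

    # ---- profiles --------------------------------------------------------
    vectors = _stage("copying vectors")(profiles.copying_vectors)(coan, assignment)
    vectors.to_csv(out / "copying_vectors.tsv", sep="\t")
    if vectors.shape[0] >= 2:
        betas = {
            c: profiles.nnls_profile(coan, assignment, c) for c in vectors.index
        }
        pd.DataFrame(betas).T.fillna(0.0).to_csv(out / "nnls_profiles.tsv", sep="\t")
        profiles.tvd_matrix(vectors).to_csv(out / "tvd.tsv", sep="\t")
        profiles.fst_matrix(panel, assignment).to_csv(out / "fst.tsv", sep="\t")

    # ---- IBD -------------------------------------------------------------
    segments = _stage("ibd detect")(ibd.detect_ibd)(panel, config.ibd_min_cm)
    segments = _stage("ibd merge")(ibd.merge_ibd)(
        segments, panel, config.merge_gap_cm, config.merge_max_discordant
    )
    segments.to_csv(out / "ibd_segments.tsv", sep="\t", index=False)
    summary = ibd.sharing_summary(segments, assignment)
    summary.to_csv(out / "sharing_summary.tsv", sep="\t")
    manifest["stages"]["ibd"] = {"n_segments": int(len(segments))}

    # ---- Ne --------------------------------------------------------------
    ne_rows = []
    for cluster, members in assignment.groupby(assignment):
        ids = list(members.index)
        if len(ids) < 10:
            continue
        seg_c = segments[
            segments["id_a"].isin(ids) & segments["id_b"].isin(ids)
        ]
        spec = demography.SegmentSpectrum.from_segments(
            seg_c, ids, chrom_lengths, min_cM=config.ne_min_cm
        )
        if spec.counts.sum() == 0:
            continue
        traj = _stage(f"ne[{cluster}]")(demography.fit_ne)(
            spec,
            G=config.ne_generations,
            n_bootstrap=config.bootstrap,
            smoothing=config.ne_smoothing,
            seed=int(np.random.SeedSequence(config.seed, spawn_key=(12,)).generate_state(1)[0] % (2**31)),
        )
        traj.table.to_csv(out / f"ne_{cluster}.tsv", sep="\t", index=False)
        for _, row in traj.at(config.ne_report_generations).iterrows():
            ne_rows.append((cluster, int(row["generation"]), row["ne"], row["lo95"], row["hi95"]))
    pd.DataFrame(
        ne_rows, columns=["cluster", "generation", "ne", "lo95", "hi95"]
    ).to_csv(out / "ne_summary.tsv", sep="\t", index=False)

    # ---- inbreeding ------------------------------------------------------
    gt = panel.genotypes()
    roh = _stage("roh")(inbreeding.detect_roh)(
        gt, panel.site_bp, panel.site_chrom, panel.individuals, config.roh
    )
    roh.to_csv(out / "roh.tsv", sep="\t", index=False)
    froh = inbreeding.f_roh(roh, panel.individuals, genome_bp=genome_bp)
    groups = assignment.map(config.cluster_groups) if config.cluster_groups else assignment
    fsnp = _stage("f_snp")(inbreeding.f_snp)(gt, panel.individuals, groups)
    fsnp["F_ROH"] = froh
    fsnp.to_csv(out / "inbreeding.tsv", sep="\t")
    manifest["stages"]["roh"] = {"n_roh": int(len(roh))}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("pipeline complete: %s", out)
    return out
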