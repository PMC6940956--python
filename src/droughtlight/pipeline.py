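"""End-to-end orchestration: simulate -> jip -> deg -> enrich -> scan -> pairs.

A run is driven by a single YAML config with explicit named thresholds
(lfc=2, fdr=0.01, enrichment alpha=0.05, min_mapping=5, scan p=1e-4 by
default) and a seed registry; the :class:`RunReport` echoes parameters,
records per-output SHA-256 checksums and stage counts, so identical config
plus inputs gives an identical report.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from . import degs, ojip, regnet, synth
from .errors import DroughtlightError, ValidationError

DEFAULT_THRESHOLDS = {
    "lfc": 2.0,
    "fdr": 0.01,
    "enrichment_alpha": 0.05,
    "min_mapping": 5,
    "scan_p_threshold": 1e-4,
    "promoter_window": 1500,
}


@dataclass
class PipelineConfig:
    out_dir: str
    stages: list[str] = field(default_factory=lambda: [
        "simulate", "jip", "deg", "enrich", "scan", "pairs"])
    seed: int = 0
    control_label: str = "control"
    treated_label: str = "drought"
    n_replicates: int = 3
    n_genes: int = 2000
    deg_fraction: float = 0.05
    effect_log2fc: float = 4.0
    dispersion: float = 0.05
    n_promoters: int = 8
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thresholds = dict(DEFAULT_THRESHOLDS)
        thresholds.update(raw.pop("thresholds", {}))
        try:
            cfg = cls(**raw, thresholds=thresholds)
        except TypeError as exc:
            raise ValidationError(f"invalid config key: {exc}") from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        known = set(DEFAULT_THRESHOLDS)
        stray = set(self.thresholds) - known
        if stray:
            raise ValidationError(f"unknown threshold keys: {sorted(stray)}")
        if not 0 <= self.thresholds["fdr"] <= 1:
            raise ValidationError("fdr threshold must be in [0, 1]")
        if not 0 < self.thresholds["enrichment_alpha"] <= 1:
            raise ValidationError("enrichment alpha must be in (0, 1]")
        unknown_stages = set(self.stages) - {
            "simulate", "jip", "deg", "enrich", "scan", "pairs"}
        if unknown_stages:
            raise ValidationError(f"unknown stages: {sorted(unknown_stages)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages in dependency order; returns the RunReport."""
    from . import __version__

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": {**{k: v for k, v in asdict(config).items() if k != "thresholds"},
                   "thresholds": dict(config.thresholds)},
        "counts": {},
        "checksums": {},
        "seeds": {"root": config.seed},
    }
    outputs: list[Path] = []
    th = config.thresholds

    matrix = truth = None
    if "simulate" in config.stages:
        # fluorescence traces: control + stressed replicates
        base = synth.TransientSpec(noise_sd=0.01)
        stress = synth.stress_spec(base)
        manifest_rows = []
        for cond, spec0 in ((config.control_label, base),
                            (config.treated_label, stress)):
            for rep in range(config.n_replicates):
                spec = replace(spec0, seed=config.seed * 1000 + rep
                               + (500 if cond == config.treated_label else 0))
                trace, _ = synth.simulate_ojip_transient(
                    spec, label=f"{cond}_{rep+1}")
                fname = out / f"transient_{cond}_{rep+1}.tsv"
                dio.write_transient(trace, fname)
                outputs.append(fname)
                manifest_rows.append({"file": fname.name, "condition": cond})
        manifest = out / "manifest.tsv"
        pd.DataFrame(manifest_rows).to_csv(manifest, sep="\t", index=False)
        outputs.append(manifest)

        matrix, truth = synth.simulate_expression_matrix(
            n_genes=config.n_genes,
            groups={config.control_label: config.n_replicates,
                    config.treated_label: config.n_replicates},
            deg_fraction=config.deg_fraction,
            effect_log2fc=config.effect_log2fc,
            dispersion=config.dispersion,
            seed=config.seed + 1,
        )
        dio.write_expression(matrix, out / "counts.tsv", out / "design.tsv")
        outputs += [out / "counts.tsv", out / "design.tsv"]
        report["counts"]["planted_degs"] = len(truth.params["deg_genes"])
        report["seeds"]["expression"] = config.seed + 1

    if "jip" in config.stages:
        manifest = out / "manifest.tsv"
        if not manifest.exists():
            raise DroughtlightError("jip stage requires the simulate stage output "
                                    "(manifest.tsv missing)")
        man = dio.read_manifest(manifest)
        rows = []
        vt_by_cond: dict[str, list] = {}
        for _, r in man.iterrows():
            trace = dio.read_transient(out / r["file"], label=r["file"])
            lm, params = ojip.analyze_transient(trace)
            rows.append({"file": r["file"], "condition": r["condition"],
                         **lm.__dict__, **{k: v for k, v in params.__dict__.items()}})
            vt_by_cond.setdefault(r["condition"], []).append(
                ojip.relative_variable_fluorescence(trace))
        jip_table = pd.DataFrame(rows)
        jip_table.to_csv(out / "jip_parameters.tsv", sep="\t", index=False)
        outputs.append(out / "jip_parameters.tsv")
        ctrl_vts = vt_by_cond.get(config.control_label, [])
        trt_vts = [v for c, vs in vt_by_cond.items()
                   if c != config.control_label for v in vs]
        if ctrl_vts and trt_vts:
            mean_curve = lambda vts: ojip.VtCurve(
                time=vts[0].time, vt=np.mean([v.vt for v in vts], axis=0))
            diff = ojip.differential_curve(mean_curve(trt_vts), mean_curve(ctrl_vts))
            pd.DataFrame({"time_s": diff.time, "delta_vt": diff.delta_vt}).to_csv(
                out / "delta_vt.tsv", sep="\t", index=False)
            outputs.append(out / "delta_vt.tsv")
            report["counts"]["delta_k_positive"] = bool(diff.delta_k > 0)
        report["counts"]["traces"] = len(rows)

    deg_result = None
    if "deg" in config.stages:
        if matrix is None:
            if not (out / "counts.tsv").exists():
                raise DroughtlightError("deg stage requires counts.tsv "
                                        "(run the simulate stage or provide inputs)")
            matrix = dio.read_expression(out / "counts.tsv", out / "design.tsv")
        deg_result = degs.deg_table(
            matrix, (config.control_label, config.treated_label),
            lfc_threshold=th["lfc"], fdr_threshold=th["fdr"])
        deg_result.rename_axis("gene").to_csv(out / "deg_table.tsv", sep="\t")
        outputs.append(out / "deg_table.tsv")
        report["counts"]["degs_up"] = int((deg_result["direction"] == "up").sum())
        report["counts"]["degs_down"] = int((deg_result["direction"] == "down").sum())

        clusters = degs.cluster_top_genes(
            matrix, n_top=min(1000, config.n_genes), k=2, seed=config.seed)
        clusters.rename_axis("gene").to_csv(out / "clusters.tsv", sep="\t")
        outputs.append(out / "clusters.tsv")

    if "enrich" in config.stages:
        if deg_result is None:
            raise DroughtlightError("enrich stage requires the deg stage")
        background = list(deg_result.index)
        query = list(deg_result.index[deg_result["direction"] != "ns"])
        # synthetic annotation: planted DEGs share a term when truth is known
        if truth is not None:
            annotation = {
                g: {"GO:PLANTED" if g in truth.params["deg_genes"] else "GO:OTHER"}
                for g in background
            }
        else:
            annotation = {g: {"GO:OTHER"} for g in background}
        enr = degs.go_enrichment(
            query, background, annotation,
            alpha=th["enrichment_alpha"], min_mapping=th["min_mapping"])
        degs.enrichment_frame(enr).to_csv(out / "enrichment.tsv", sep="\t",
                                          index=False)
        outputs.append(out / "enrichment.tsv")
        report["counts"]["enriched_terms"] = sum(e.enriched for e in enr)

    hits = None
    promoters = motif2tf = None
    if "scan" in config.stages:
        motifs = regnet.packaged_motifs()
        rng = np.random.default_rng(config.seed + 2)
        pairs_fixture = regnet.load_packaged_pairs()
        # wire each packaged motif to a distinct fixture pair of its TF family
        # and plant a consensus site in that pair's target promoter
        used, planted, motif2tf, targets = set(), [], {}, []
        for motif in motifs:
            pair = next((p for p in pairs_fixture
                         if p.tf_family == motif.tf_family
                         and (p.tf_gene, p.target_gene) not in used), None)
            if pair is None:
                continue
            used.add((pair.tf_gene, pair.target_gene))
            motif2tf[motif.motif_id] = pair.tf_gene
            if pair.target_gene not in targets:
                targets.append(pair.target_gene)
            offset = int(rng.integers(0, th["promoter_window"] - len(motif)))
            planted.append((motif.matrix, targets.index(pair.target_gene),
                            offset, "+"))
        records, _ = synth.simulate_promoter_set(
            n_seqs=len(targets), length=th["promoter_window"],
            planted=planted, seed=config.seed + 2, seq_ids=targets)
        dio.write_fasta(records, out / "promoters.fasta")
        outputs.append(out / "promoters.fasta")
        promoters = {r.id: str(r.seq) for r in records}
        hits = regnet.scan_promoters(
            motifs, promoters, p_threshold=th["scan_p_threshold"])
        regnet.hits_frame(hits).to_csv(out / "hits.tsv", sep="\t", index=False)
        outputs.append(out / "hits.tsv")
        report["counts"]["hits"] = len(hits)
        report["seeds"]["promoters"] = config.seed + 2

    if "pairs" in config.stages:
        if hits is None or motif2tf is None:
            raise DroughtlightError("pairs stage requires the scan stage")
        fixture = regnet.load_packaged_pairs()
        tf_degs = pd.DataFrame(
            {"fold_change": [p.tf_fold_change for p in fixture],
             "fdr": [p.tf_fdr for p in fixture]},
            index=[p.tf_gene for p in fixture]).groupby(level=0).first()
        target_degs = pd.DataFrame(
            {"fold_change": [p.target_fold_change for p in fixture],
             "fdr": [p.target_fdr for p in fixture]},
            index=[p.target_gene for p in fixture]).groupby(level=0).first()
        pairs = regnet.designate_pairs(
            tf_degs, hits, motif2tf, target_degs,
            tf_families={p.tf_gene: p.tf_family for p in fixture})
        regnet.pairs_frame(pairs).to_csv(out / "pairs.tsv", sep="\t", index=False)
        dio.write_json(regnet.summarize_pairs(pairs), out / "pairs_summary.json")
        outputs += [out / "pairs.tsv", out / "pairs_summary.json"]
        report["counts"]["pairs"] = len(pairs)

    report["checksums"] = {p.name: _sha256(p) for p in outputs}
    dio.write_json(report, out / "run_report.json")
    return report
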