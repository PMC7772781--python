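"""Config-driven orchestration of the analysis stages.

A single YAML/JSON config names the input files (peaks per factor, gene
table, enhancer annotation, expression table, eRNA BED, coverage tracks)
and overrides any analysis parameter. ``run`` executes the stages in
dependency order, writes every result as TSV/JSON/BED into the output
directory, and finishes with a manifest of (file, stage, sha256) so a rerun
on identical inputs can be verified checksum-for-checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ernas as ernas_mod
from . import expression_integration as expr_mod
from .enrichment import compare_classes, occupancy_fold_change, region_density, shuffle_intervals
from .genomic_io import (
    parse_bed,
    parse_bedgraph,
    parse_enhancers,
    parse_expression,
    parse_gene_table,
    parse_narrowpeak,
    to_rpm,
    write_bed,
)
from .metagene import anchored_heatmap, expression_strata, quantile_normalize, scaled_gene_profile, tss_window_profile
from .occupancy import call_occupancy, classify_states, predict_active_enhancers, venn_counts
from .positional import factor_offset_summary, pair_nelfa_ctr9

logger = logging.getLogger(__name__)

DEFAULT_PARAMS = {
    "bin_width": 10,
    "assignment_window": 2000,
    "genic_flank": 2000,
    "promoter_exclusion": 1000,
    "max_association_distance": 100_000,
    "expressed_threshold": 1.0,
    "tss_window_bp": 4000,
    "heatmap_window_bp": 2000,
    "flank_bp": 2000,
    "body_bins": 60,
    "flank_bins": 20,
    "shuffle_seed": 0,
}

OFFSET_FACTORS = ("NELFA", "Ser5p", "Ctr9")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    peaks: dict[str, str] = field(default_factory=dict)
    tracks: dict[str, str] = field(default_factory=dict)
    tracks_knockdown: dict[str, str] = field(default_factory=dict)
    genes: str | None = None
    enhancers: str | None = None
    expression: str | None = None
    ernas: str | None = None
    genome: str | None = None
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        inputs = raw.get("inputs", {})
        return cls(
            outdir=raw["outdir"],
            seed=int(raw.get("seed", 0)),
            peaks=dict(inputs.get("peaks", {})),
            tracks=dict(inputs.get("tracks", {})),
            tracks_knockdown=dict(inputs.get("tracks_knockdown", {})),
            genes=inputs.get("genes"),
            enhancers=inputs.get("enhancers"),
            expression=inputs.get("expression"),
            ernas=inputs.get("ernas"),
            genome=inputs.get("genome"),
            params=dict(raw.get("params", {})),
        )

    def param(self, key: str):
        return self.params.get(key, DEFAULT_PARAMS[key])

    def validate(self) -> None:
        missing = []
        for label, path in self.iter_paths():
            if not Path(path).exists():
                missing.append(f"{label}: {path}")
        if missing:
            raise FileNotFoundError("missing input files: " + "; ".join(missing))

    def iter_paths(self):
        for factor, p in sorted(self.peaks.items()):
            yield f"peaks[{factor}]", p
        for factor, p in sorted(self.tracks.items()):
            yield f"tracks[{factor}]", p
        for factor, p in sorted(self.tracks_knockdown.items()):
            yield f"tracks_knockdown[{factor}]", p
        for label in ("genes", "enhancers", "expression", "ernas", "genome"):
            p = getattr(self, label)
            if p is not None:
                yield label, p


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=1)
        fh.write("\n")


def run(config: PipelineConfig) -> dict:
    """Execute every stage the configured inputs support; returns the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict[str, str]] = []

    def emit(path: Path, stage: str) -> None:
        manifest.append({"file": path.name, "stage": stage, "sha256": _sha256(path)})

    def stage(name: str):
        def wrap(fn):
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - report stage and re-raise
                raise PipelineError(name, exc) from exc
        return wrap

    # ---- io ---------------------------------------------------------------
    peaks = {f: parse_narrowpeak(p, f) for f, p in sorted(config.peaks.items())}
    genes = parse_gene_table(config.genes) if config.genes else []
    enhancers = parse_enhancers(config.enhancers) if config.enhancers else []
    expression = parse_expression(config.expression) if config.expression else []
    erna_ivs = parse_bed(config.ernas) if config.ernas else []
    genome = json.loads(Path(config.genome).read_text()) if config.genome else {}
    bw = int(config.param("bin_width"))
    tracks = {f: to_rpm(parse_bedgraph(p, bw)) for f, p in sorted(config.tracks.items())}
    tracks_kd = {f: to_rpm(parse_bedgraph(p, bw)) for f, p in sorted(config.tracks_knockdown.items())}

    matrix = None
    if enhancers and peaks:
        @stage("occupancy")
        def _occupancy():
            nonlocal matrix
            matrix = call_occupancy(enhancers, peaks)
            path = outdir / "occupancy.tsv"
            matrix.table.astype(int).to_csv(path, sep="\t", index_label="region_id")
            emit(path, "occupancy")
            if all(f in peaks for f in ("H3K27ac", "H3K4me1", "Ctr9")):
                states = classify_states(matrix)
                spath = outdir / "enhancer_states.tsv"
                with open(spath, "w") as fh:
                    fh.write("region_id\tstate\tctr9_bound\n")
                    for s in states:
                        fh.write(f"{s.region_id}\t{s.state}\t{int(s.ctr9_bound)}\n")
                emit(spath, "occupancy")
                vpath = outdir / "venn_counts.json"
                _dump_json(venn_counts(matrix, ["H3K27ac", "H3K4me1", "Ctr9"]), vpath)
                emit(vpath, "occupancy")

    if genes and peaks:
        @stage("positional")
        def _positional():
            path = outdir / "tss_offsets.tsv"
            with open(path, "w") as fh:
                fh.write("factor\tn\tmean\tmedian\tq25\tq75\n")
                for factor in OFFSET_FACTORS:
                    if factor not in peaks:
                        continue
                    s = factor_offset_summary(
                        peaks[factor], genes, int(config.param("assignment_window")), factor
                    )
                    fh.write(
                        f"{s.factor}\t{s.n}\t{s.mean:.3f}\t{s.median:.3f}\t{s.q25:.3f}\t{s.q75:.3f}\n"
                    )
            emit(path, "positional")
            if enhancers and "NELFA" in peaks and "Ctr9" in peaks:
                pairs = pair_nelfa_ctr9(enhancers, peaks["NELFA"], peaks["Ctr9"])
                ppath = outdir / "nelfa_ctr9_pairs.tsv"
                with open(ppath, "w") as fh:
                    fh.write("region_id\tnelfa_summit\tnearest_ctr9\tdistance\tlaterality\n")
                    for pr in pairs:
                        d = "NA" if pr.distance is None else f"{pr.distance:.0f}"
                        c = "NA" if pr.nearest_ctr9 is None else str(pr.nearest_ctr9)
                        fh.write(f"{pr.region_id}\t{pr.nelfa_summit}\t{c}\t{d}\t{pr.laterality}\n")
                emit(ppath, "positional")

    if enhancers and "Ctr9" in tracks:
        @stage("enrichment")
        def _enrichment():
            dens = region_density(tracks["Ctr9"], enhancers, "Ctr9")
            path = outdir / "ctr9_density.tsv"
            with open(path, "w") as fh:
                fh.write("region_id\tclass\tdensity\tmass\tlength\n")
                for d in dens:
                    fh.write(f"{d.region_id}\t{d.enh_class}\t{d.density:.6g}\t{d.mass:.6g}\t{d.length}\n")
            emit(path, "enrichment")
            contrast = compare_classes(dens, "SE", "TE")
            cpath = outdir / "class_contrast.json"
            _dump_json(
                {
                    "fold": contrast.fold,
                    "p_value": contrast.p_value,
                    "mean_SE": contrast.mean_a,
                    "mean_TE": contrast.mean_b,
                    "n_SE": contrast.n_a,
                    "n_TE": contrast.n_b,
                },
                cpath,
            )
            emit(cpath, "enrichment")
            if genome:
                shuffled = shuffle_intervals(enhancers, genome, config.seed)
                spath = outdir / "shuffled_control.bed"
                write_bed(shuffled, spath)
                emit(spath, "enrichment")

    if enhancers and "Ser2p" in tracks and "Ser2p" in tracks_kd:
        @stage("knockdown_occupancy")
        def _knockdown():
            by_class = {
                cls: [e for e in enhancers if e.enh_class == cls] for cls in ("SE", "TE")
            }
            folds = occupancy_fold_change(tracks["Ser2p"], tracks_kd["Ser2p"], by_class)
            path = outdir / "ser2p_knockdown_folds.json"
            _dump_json(folds, path)
            emit(path, "knockdown_occupancy")

    if genes and tracks and expression:
        @stage("metagene")
        def _metagene():
            strata = expression_strata(expression, float(config.param("expressed_threshold")))
            by_id = {g.gene_id: g for g in genes}
            path = outdir / "metagene_profiles.tsv"
            with open(path, "w") as fh:
                fh.write("factor\tstratum\tbin\tvalue\n")
                for factor, track in tracks.items():
                    for stratum, ids in strata.items():
                        gene_set = [by_id[i] for i in ids if i in by_id]
                        prof = scaled_gene_profile(
                            track,
                            gene_set,
                            int(config.param("flank_bp")),
                            int(config.param("body_bins")),
                            int(config.param("flank_bins")),
                            scale_to_reads=1e7,
                        )
                        for b, v in enumerate(prof.values):
                            fh.write(f"{factor}\t{stratum}\t{b}\t{v:.6g}\n")
            emit(path, "metagene")
            tpath = outdir / "tss_profiles.tsv"
            with open(tpath, "w") as fh:
                fh.write("factor\tbin\tvalue\n")
                for factor, track in tracks.items():
                    vec = tss_window_profile(track, genes, int(config.param("tss_window_bp")))
                    for b, v in enumerate(vec):
                        fh.write(f"{factor}\t{b}\t{v:.6g}\n")
            emit(tpath, "metagene")
            if enhancers and "NELFA" in peaks and "Ctr9" in peaks:
                pairs = pair_nelfa_ctr9(enhancers, peaks["NELFA"], peaks["Ctr9"])
                mats = anchored_heatmap(tracks, pairs, int(config.param("heatmap_window_bp")))
                normed = quantile_normalize({k: m.matrix for k, m in mats.items()})
                for factor, mat in sorted(normed.items()):
                    hpath = outdir / f"heatmap_{factor}.tsv"
                    np.savetxt(hpath, mat, delimiter="\t", fmt="%.6g")
                    emit(hpath, "metagene")

    if expression and genes and enhancers:
        @stage("expression_integration")
        def _expression():
            expressed = expr_mod.filter_expressed(expression, float(config.param("expressed_threshold")))
            groups_map = expr_mod.associate_genes(
                genes, enhancers, int(config.param("max_association_distance"))
            )
            path = outdir / "ma_plot.tsv"
            lfcs: dict[str, list[float]] = {"SE": [], "TE": [], "other": []}
            with open(path, "w") as fh:
                fh.write("gene_id\ttpm_control\ttpm_knockdown\tlog2fc\tgroup\n")
                for rec in expressed:
                    lfc = expr_mod.log2_fold_change(rec)
                    group = groups_map.get(rec.gene_id, "other")
                    lfcs[group].append(lfc)
                    fh.write(
                        f"{rec.gene_id}\t{rec.tpm_control:.6g}\t{rec.tpm_knockdown:.6g}\t{lfc:.4f}\t{group}\n"
                    )
            emit(path, "expression_integration")
            nonempty = {g: v for g, v in lfcs.items() if v}
            contrast = expr_mod.group_contrast(nonempty)
            cpath = outdir / "expression_contrast.json"
            _dump_json(
                {
                    "n": contrast.n,
                    "median_log2fc": contrast.median_log2fc,
                    "fraction_decreased": contrast.fraction_decreased,
                    "pairwise_p": {f"{a}_vs_{b}": p for (a, b), p in contrast.pairwise_p.items()},
                },
                cpath,
            )
            emit(cpath, "expression_integration")

    if enhancers and erna_ivs is not None and matrix is not None and config.ernas:
        if "Ctr9" in matrix.table.columns and "Ser2p" in matrix.table.columns:
            @stage("ernas")
            def _ernas():
                calls, summary = ernas_mod.call_erna(enhancers, erna_ivs, matrix)
                path = outdir / "erna_calls.tsv"
                with open(path, "w") as fh:
                    fh.write("region_id\terna\tctr9\tser2p\n")
                    for c in calls:
                        fh.write(
                            f"{c.region_id}\t{int(c.erna_present)}\t{int(c.ctr9_bound)}\t{int(c.ser2p_bound)}\n"
                        )
                emit(path, "ernas")
                spath = outdir / "erna_summary.json"
                _dump_json(summary, spath)
                emit(spath, "ernas")

    if "H3K27ac" in peaks and "Ctr9" in peaks and genes:
        @stage("prediction")
        def _prediction():
            predicted = predict_active_enhancers(
                peaks["H3K27ac"], peaks["Ctr9"], genes, int(config.param("promoter_exclusion"))
            )
            path = outdir / "predicted_active_enhancers.bed"
            write_bed(predicted, path)
            emit(path, "prediction")

    manifest_obj = {"outputs": sorted(manifest, key=lambda m: m["file"])}
    mpath = outdir / "manifest.json"
    _dump_json(manifest_obj, mpath)
    return manifest_obj
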