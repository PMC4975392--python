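"""End-to-end orchestration of the analysis stages.

Stage order: ref -> annotate -> cpg -> quantify -> cluster -> dmr ->
crm -> regions -> kegg -> go.  Each stage reads the upstream TSV/BED
outputs from the result directory, so stages can be re-run
individually; a completed stage (all outputs present) is skipped unless
forced.  A JSON manifest records the configuration, seed and per-stage
timings of every run, and a rerun with an unchanged configuration is
byte-identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .cpg_islands import IslandParams, find_islands, islands_to_bed
from .differential import bh_fdr, call_crms, call_dmrs, compare_region_levels
from .enrichment import go_enrich, kegg_pathway_test, link_peaks_to_genes, link_peaks_to_pathways
from .intervals import (
    GenomicInterval,
    RefPeak,
    RefPeakSet,
    annotate_peaks,
    derive_feature_windows,
)
from .io_formats import (
    read_bed,
    read_fasta,
    read_gene_models_bed12,
    read_mapping_table,
    read_obo_subset,
    read_repeats_bed4,
    write_bed,
    write_table,
)
from .quantify import (
    PeakMatrix,
    build_peak_matrix,
    build_region_sets,
    build_region_matrix,
    cluster_peaks,
    dendrogram_to_newick,
)

log = logging.getLogger("coldmeth")

STAGES = ("ref", "annotate", "cpg", "quantify", "cluster", "dmr", "crm",
          "regions", "kegg", "go")


@dataclass
class PipelineConfig:
    """All input paths and thresholds for one pipeline run.

    Threshold defaults are the study's printed parameters: 2-fold and
    FDR <= 0.01 for DMRs; GC >= 55, O/E >= 0.65, length >= 500 for CpG
    islands; p <= 0.05 with median RPM ratio outside [1/1.1, 1.1] for
    pathways; p <= 0.05 with ratio >= 1.3 (1.5 for the figure tier,
    FDR < 0.2 for the table tier) for GO; promoter = 3 kb upstream,
    downstream = 5 kb, TSS window = +/- 1 kb.
    """

    outdir: str = "results"
    genome_fasta: str = ""
    gene_models: str = ""
    repeats: str = ""
    tx2gene: str = ""
    tx2ko: str = ""
    ko2pathway: str = ""
    gene2go: str = ""
    ontology: str = ""
    peaks: dict = field(default_factory=dict)  # sample -> BED path
    reads: dict = field(default_factory=dict)  # sample -> BED path
    control: str = "28C"
    treatments: tuple = ("18C_5d", "18C_30d")
    fold_min: float = 2.0
    q_max: float = 0.01
    gc_min: float = 55.0
    oe_min: float = 0.65
    len_min: int = 500
    kegg_p: float = 0.05
    kegg_ratio: float = 1.1
    go_ratio: float = 1.3
    go_ratio_figure: float = 1.5
    go_p: float = 0.05
    go_fdr: float = 0.2
    promoter_bp: int = 3000
    downstream_bp: int = 5000
    tss_half: int = 1000
    pseudocount: float = 0.5
    min_peaks: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fold_min", "q_max", "gc_min", "oe_min", "len_min",
                     "kegg_p", "kegg_ratio", "go_ratio", "go_p", "go_fdr",
                     "promoter_bp", "downstream_bp", "tss_half", "min_peaks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "treatments" in data:
            data["treatments"] = tuple(data["treatments"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["treatments"] = list(self.treatments)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @property
    def samples(self) -> list[str]:
        return [self.control, *self.treatments]

    @property
    def comparisons(self) -> list[tuple[str, str]]:
        pairs = [(t, self.control) for t in self.treatments]
        if len(self.treatments) >= 2:
            pairs.append((self.treatments[1], self.treatments[0]))
        return pairs


class _Workspace:
    """Lazy loading and caching of inputs and intermediate results."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self._cache: dict = {}

    def _get(self, key, builder):
        if key not in self._cache:
            self._cache[key] = builder()
        return self._cache[key]

    @property
    def annotation(self):
        def build():
            tx2gene = read_mapping_table(self.cfg.tx2gene, ["transcript_id", "gene_id"])
            ann = read_gene_models_bed12(
                self.cfg.gene_models, dict(zip(tx2gene["transcript_id"], tx2gene["gene_id"]))
            )
            ann.repeats = read_repeats_bed4(self.cfg.repeats)
            return ann
        return self._get("annotation", build)

    @property
    def genome(self):
        return self._get("genome", lambda: read_fasta(self.cfg.genome_fasta))

    @property
    def chrom_sizes(self):
        return self._get(
            "chrom_sizes", lambda: {r.name: len(r.sequence) for r in self.genome}
        )

    @property
    def windows(self):
        return self._get(
            "windows",
            lambda: derive_feature_windows(
                self.annotation, self.chrom_sizes,
                promoter_bp=self.cfg.promoter_bp,
                downstream_bp=self.cfg.downstream_bp,
                tss_half=self.cfg.tss_half,
            ),
        )

    @property
    def ref(self) -> RefPeakSet:
        def build():
            path = self.out / "ref_peaks.bed"
            ivs = read_bed(path, min_cols=6)
            return RefPeakSet([
                RefPeak(iv.attrs[0], GenomicInterval(iv.chrom, iv.start, iv.end),
                        frozenset(iv.attrs[3].split(",")) if len(iv.attrs) > 3 else frozenset())
                for iv in ivs
            ])
        return self._get("ref", build)

    @property
    def reads(self):
        return self._get(
            "reads",
            lambda: {s: read_bed(p) for s, p in self.cfg.reads.items()},
        )

    @property
    def matrix(self) -> PeakMatrix:
        def build():
            df = pd.read_csv(self.out / "peak_matrix.tsv", sep="\t")
            samples = self.cfg.samples
            counts = df.set_index("peak_id")[[f"count_{s}" for s in samples]]
            counts.columns = samples
            libs = pd.Series(
                {s: int(df[f"lib_{s}"].iloc[0]) for s in samples}
            )
            return PeakMatrix(ref=self.ref, samples=samples, counts=counts, lib_sizes=libs)
        return self._get("matrix", build)

    def dmr_table(self, treat: str) -> pd.DataFrame:
        key = f"dmr_{treat}"
        path = self.out / f"dmr_{treat}_vs_{self.cfg.control}.tsv"
        return self._get(key, lambda: pd.read_csv(path, sep="\t"))


def _stage_ref(ws: _Workspace) -> list[Path]:
    from .intervals import merge_peak_sets

    peak_sets = {s: read_bed(p) for s, p in ws.cfg.peaks.items()}
    ref = merge_peak_sets(peak_sets)
    ws._cache["ref"] = ref
    out = ws.out / "ref_peaks.bed"
    write_bed(
        [
            GenomicInterval(
                p.chrom, p.start, p.end,
                attrs=(p.peak_id, "0", ".", ",".join(sorted(p.source_samples))),
            )
            for p in ref
        ],
        out,
    )
    return [out]


def _stage_annotate(ws: _Workspace) -> list[Path]:
    labels = annotate_peaks(ws.ref, ws.windows)
    out = ws.out / "peak_annotation.tsv"
    df = pd.DataFrame(sorted(labels.items()), columns=["peak_id", "label"])
    write_table(df, out)
    return [out]


def _stage_cpg(ws: _Workspace) -> list[Path]:
    params = IslandParams(gc_min=ws.cfg.gc_min, oe_min=ws.cfg.oe_min, len_min=ws.cfg.len_min)
    islands = []
    for rec in ws.genome:
        islands.extend(find_islands(rec, params))
    ws._cache["islands"] = islands
    out = ws.out / "islands.bed"
    write_bed(islands_to_bed(islands), out)
    return [out]


def _stage_quantify(ws: _Workspace) -> list[Path]:
    matrix = build_peak_matrix(ws.ref, ws.reads)
    ws._cache["matrix"] = matrix
    coords = pd.DataFrame(
        {
            "peak_id": [p.peak_id for p in ws.ref],
            "chrom": [p.chrom for p in ws.ref],
            "start": [p.start for p in ws.ref],
            "end": [p.end for p in ws.ref],
        }
    )
    df = coords.copy()
    rpm = matrix.rpm
    for s in matrix.samples:
        df[f"count_{s}"] = matrix.counts[s].to_numpy()
    for s in matrix.samples:
        df[f"rpm_{s}"] = rpm[s].to_numpy()
    for s in matrix.samples:
        df[f"lib_{s}"] = int(matrix.lib_sizes[s])
    out = ws.out / "peak_matrix.tsv"
    write_table(df, out)
    return [out]


def _stage_cluster(ws: _Workspace) -> list[Path]:
    dend = cluster_peaks(ws.matrix)
    out = ws.out / "dendrogram.nwk"
    out.write_text(dendrogram_to_newick(dend) + "\n")
    return [out]


def _stage_dmr(ws: _Workspace) -> list[Path]:
    outs = []
    for treat, control in ws.cfg.comparisons[: len(ws.cfg.treatments)]:
        table = call_dmrs(
            ws.matrix, treat, control,
            fold_min=ws.cfg.fold_min, q_max=ws.cfg.q_max,
            pseudocount=ws.cfg.pseudocount,
        )
        out = ws.out / f"dmr_{treat}_vs_{control}.tsv"
        write_table(table, out)
        outs.append(out)
    return outs


def _stage_crm(ws: _Workspace) -> list[Path]:
    t5, t30 = ws.cfg.treatments[0], ws.cfg.treatments[1]
    crm = call_crms(ws.dmr_table(t5), ws.dmr_table(t30))
    out = ws.out / "crm.tsv"
    write_table(crm, out)
    return [out]


def _stage_regions(ws: _Workspace) -> list[Path]:
    params = IslandParams(gc_min=ws.cfg.gc_min, oe_min=ws.cfg.oe_min, len_min=ws.cfg.len_min)
    islands = ws._cache.get("islands")
    if islands is None:
        islands = []
        for rec in ws.genome:
            islands.extend(find_islands(rec, params))
    region_sets = build_region_sets(ws.windows, islands, ws.annotation)
    matrices = build_region_matrix(region_sets, ws.reads)
    outs = []
    for cls in sorted(matrices):
        out = ws.out / f"region_{cls}.tsv"
        write_table(matrices[cls].rename_axis("instance_id").reset_index(), out)
        outs.append(out)
    comparisons = compare_region_levels(matrices, ws.cfg.comparisons)
    out = ws.out / "region_comparisons.tsv"
    write_table(comparisons, out)
    outs.append(out)
    return outs


def _kegg_links(ws: _Workspace):
    tx2gene = read_mapping_table(ws.cfg.tx2gene, ["transcript_id", "gene_id"])
    peak_genes = link_peaks_to_genes(
        ws.ref, ws.windows, dict(zip(tx2gene["transcript_id"], tx2gene["gene_id"]))
    )
    return tx2gene, peak_genes


def _stage_kegg(ws: _Workspace) -> list[Path]:
    tx2gene, peak_genes = _kegg_links(ws)
    tx2ko = read_mapping_table(ws.cfg.tx2ko, ["transcript_id", "ko_id"])
    ko2pathway = read_mapping_table(ws.cfg.ko2pathway, ["ko_id", "pathway_id"])
    pw_peaks = link_peaks_to_pathways(peak_genes, tx2gene, tx2ko, ko2pathway)
    outs = []
    for treat, control in ws.cfg.comparisons:
        table = kegg_pathway_test(
            ws.matrix, pw_peaks, treat, control,
            min_peaks=ws.cfg.min_peaks, pseudocount=ws.cfg.pseudocount,
            p_max=ws.cfg.kegg_p, ratio_band=ws.cfg.kegg_ratio,
        )
        out = ws.out / f"kegg_{treat}_vs_{control}.tsv"
        write_table(table, out)
        outs.append(out)
    return outs


def _stage_go(ws: _Workspace) -> list[Path]:
    _, peak_genes = _kegg_links(ws)
    gene2go = read_mapping_table(ws.cfg.gene2go, ["gene_id", "go_id"])
    ontology = read_obo_subset(ws.cfg.ontology)
    background = sorted(set(peak_genes["gene_id"]))
    dmr_peaks: set[str] = set()
    for treat in ws.cfg.treatments:
        table = ws.dmr_table(treat)
        dmr_peaks |= set(table[table["is_dmr"]]["peak_id"])
    fg = sorted(set(peak_genes[peak_genes["peak_id"].isin(dmr_peaks)]["gene_id"]))
    result = go_enrich(
        fg, background, gene2go, ontology,
        ratio_min=ws.cfg.go_ratio, p_max=ws.cfg.go_p,
        fdr_max=ws.cfg.go_fdr, figure_ratio_min=ws.cfg.go_ratio_figure,
    )
    out = ws.out / "go_enrichment.tsv"
    write_table(result, out)
    return [out]


_STAGE_FUNCS = {
    "ref": _stage_ref,
    "annotate": _stage_annotate,
    "cpg": _stage_cpg,
    "quantify": _stage_quantify,
    "cluster": _stage_cluster,
    "dmr": _stage_dmr,
    "crm": _stage_crm,
    "regions": _stage_regions,
    "kegg": _stage_kegg,
    "go": _stage_go,
}

_STAGE_OUTPUTS = {
    "ref": ["ref_peaks.bed"],
    "annotate": ["peak_annotation.tsv"],
    "cpg": ["islands.bed"],
    "quantify": ["peak_matrix.tsv"],
    "cluster": ["dendrogram.nwk"],
    "crm": ["crm.tsv"],
    "regions": ["region_comparisons.tsv"],
    "go": ["go_enrichment.tsv"],
}


def _stage_done(ws: _Workspace, stage: str) -> bool:
    if stage == "dmr":
        names = [
            f"dmr_{t}_vs_{ws.cfg.control}.tsv" for t in ws.cfg.treatments
        ]
    elif stage == "kegg":
        names = [f"kegg_{t}_vs_{c}.tsv" for t, c in ws.cfg.comparisons]
    else:
        names = _STAGE_OUTPUTS[stage]
    return all((ws.out / n).exists() for n in names)


def run_pipeline(
    config: PipelineConfig,
    stages: Sequence[str] | None = None,
    force: bool = False,
) -> dict:
    """Execute the requested stages (all by default) in pipeline order.

    Completed stages are skipped unless ``force``; outputs land in
    ``config.outdir`` together with a JSON run manifest.
    """
    ws = _Workspace(config)
    wanted = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
    }
    outputs: dict = {}
    for stage in wanted:
        if not force and _stage_done(ws, stage):
            log.info("stage %s: up to date, skipped", stage)
            outputs[stage] = []
            manifest["stages"][stage] = {"skipped": True}
            continue
        t0 = time.time()
        try:
            outs = _STAGE_FUNCS[stage](ws)
        except FileNotFoundError as exc:
            raise RuntimeError(f"stage {stage!r}: missing input ({exc})") from exc
        dt = time.time() - t0
        log.info("stage %s: %.1fs, %d output(s)", stage, dt, len(outs))
        outputs[stage] = outs
        manifest["stages"][stage] = {
            "seconds": round(dt, 3),
            "outputs": [p.name for p in outs],
        }
    with open(ws.out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return outputs


def simulate_inputs(seed: int, outdir: str | Path, sim_config=None) -> PipelineConfig:
    """Generate a synthetic study and return a config pointing at it."""
    from .synthetic_data import SAMPLES, SimConfig, simulate, write_study

    sim = sim_config or SimConfig(seed=seed)
    study = simulate(sim)
    outdir = Path(outdir)
    paths = write_study(study, outdir / "inputs")
    return PipelineConfig(
        outdir=str(outdir / "results"),
        genome_fasta=str(paths["genome"]),
        gene_models=str(paths["gene_models"]),
        repeats=str(paths["repeats"]),
        tx2gene=str(paths["tx2gene"]),
        tx2ko=str(paths["tx2ko"]),
        ko2pathway=str(paths["ko2pathway"]),
        gene2go=str(paths["gene2go"]),
        ontology=str(paths["ontology"]),
        peaks={s: str(paths[f"peaks_{s}"]) for s in SAMPLES},
        reads={s: str(paths[f"reads_{s}"]) for s in SAMPLES},
        seed=seed,
    )
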