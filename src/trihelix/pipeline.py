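"""End-to-end orchestration: simulate inputs, identify the family, build the
catalog, classify duplications with Ka/Ks, build the phylogeny, scan
promoters, and quantify expression — from a single validated config with
deterministic per-stage seeds and a provenance log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq
from pydantic import BaseModel, ConfigDict, ValidationError as PydanticValidationError

import trihelix
from trihelix import (
    catalog as cat,
    domain_search as ds,
    duplication_synteny as dup,
    expression as ex,
    io as tio,
    motifs_elements as me,
    phylogeny as ph,
    synthetic_data as sd,
)
from trihelix.errors import PipelineError, ValidationError

STAGES = (
    "simulate",
    "identify",
    "catalog",
    "duplications",
    "phylogeny",
    "elements",
    "expression",
)


class PipelineConfig(BaseModel):
    """All stage parameters with survey-matching defaults.

    ``collinearity_max_gap`` defaults to 3 at the bundled synthetic scale
    (~25 genes per chromosome); use the MCScanX default of 25 for real
    genomes, where chromosomes carry thousands of genes.  ``bootstrap
    replicates`` defaults to 100 for desk-scale runs; the survey setting is
    1000.
    """

    model_config = ConfigDict(extra="forbid")

    rng_seed: int = 0
    stages: tuple[str, ...] = STAGES

    # identification
    e_threshold: float = 0.01
    pass1_e_threshold: float = 5.0
    min_model_coverage: float = 0.8
    n_calibration_shuffles: int = 1000

    # duplication / synteny
    tandem_window: int = 200_000
    min_anchors: int = 5
    collinearity_max_gap: int = 3
    anchor_score_threshold: float = 60.0
    anchor_top_k: int = 5

    # phylogeny
    bootstrap_replicates: int = 100

    # promoters / elements
    promoter_length: int = 1500

    # expression
    expression_groups: int = 5
    ct_noise_sd: float = 0.2

    # synthetic-data scale
    n_family: int = 20
    n_decoy: int = 80
    n_subfamilies: int = 5
    genome_family: int = 14
    genome_decoy: int = 100
    genome_chromosomes: int = 4
    tandem_clusters: tuple[tuple[int, int, int], ...] = ((0, 2, 150_000), (1, 2, 150_000))
    segmental_blocks: tuple[tuple[int, float], ...] = ((8, 0.05),)
    expression_genes: int = 40
    qpcr_genes: int = 12
    qpcr_timepoints: tuple[str, ...] = ("t1", "t6", "t12", "t24")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the root seed."""
        return (self.rng_seed * 1000 + STAGES.index(stage)) % (2**31 - 1)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for key in ("tandem_clusters", "segmental_blocks"):
        if key in data:
            data[key] = tuple(tuple(x) for x in data[key])
    if "qpcr_timepoints" in data:
        data["qpcr_timepoints"] = tuple(data["qpcr_timepoints"])
    if "stages" in data:
        data["stages"] = tuple(data["stages"])
    try:
        return PipelineConfig(**data)
    except PydanticValidationError as err:
        raise ValidationError(str(err)) from err


def dump_config(config: PipelineConfig) -> str:
    data = config.model_dump()
    data["stages"] = list(data["stages"])
    data["tandem_clusters"] = [list(x) for x in data["tandem_clusters"]]
    data["segmental_blocks"] = [list(x) for x in data["segmental_blocks"]]
    data["qpcr_timepoints"] = list(data["qpcr_timepoints"])
    return yaml.safe_dump(data, sort_keys=True)


@dataclass
class ReportBundle:
    """Artifacts produced by one pipeline run: stage name -> file path(s),
    plus the provenance log."""

    out_dir: Path
    artifacts: dict[str, Path] = field(default_factory=dict)
    log: dict = field(default_factory=dict)

    def path(self, name: str) -> Path:
        if name not in self.artifacts:
            raise PipelineError(f"missing upstream artifact '{name}'")
        return self.artifacts[name]


def _require(bundle: ReportBundle, name: str, stage: str) -> Path:
    path = bundle.artifacts.get(name)
    if path is None or not Path(path).exists():
        raise PipelineError(
            f"stage '{stage}' requires artifact '{name}'; run its upstream stage first"
        )
    return Path(path)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(config: PipelineConfig, bundle: ReportBundle) -> None:
    seed = config.stage_seed("simulate")
    out = bundle.out_dir

    profile = ds.build_profile(sd.make_seed_alignment())
    ds.save_profile(profile, out / "seed_profile.txt")

    spec = sd.FamilyGenomeSpec(
        n_family=config.n_family, n_decoy=config.n_decoy, rng_seed=seed
    )
    proteome, prot_truth = sd.generate_proteome(
        spec, seed_profile=profile, n_subfamilies=config.n_subfamilies
    )
    tio.write_fasta(proteome, out / "proteome.fasta")
    prot_truth.to_csv(out / "proteome_truth.tsv", sep="\t")

    genome_spec = sd.FamilyGenomeSpec(
        n_family=config.genome_family,
        n_decoy=config.genome_decoy,
        n_chromosomes=config.genome_chromosomes,
        tandem_clusters=config.tandem_clusters,
        segmental_blocks=config.segmental_blocks,
        promoter_implants={e.element_id: 1.0 for e in me.load_element_library()},
        rng_seed=seed + 1,
    )
    genome = sd.generate_duplicated_genome(
        genome_spec, seed_profile=profile, promoter_length=config.promoter_length
    )
    tio.write_fasta(genome.chromosomes, out / "genome.fasta")
    tio.write_gff3(genome.gff_features, out / "genome.gff3")
    genome.truth.to_csv(out / "genome_truth.tsv", sep="\t")
    (out / "genome_cds.fasta").write_text(
        "".join(f">{g.gene_id}\n{g.cds}\n" for g in genome.genes)
    )

    matrix, groups = sd.generate_expression_matrix(
        config.expression_genes, n_groups=config.expression_groups, rng_seed=seed + 2
    )
    matrix.to_csv(out / "expression_matrix.tsv", sep="\t")
    groups.to_csv(out / "expression_truth.tsv", sep="\t")

    genes = [f"gene{k + 1:03d}" for k in range(config.qpcr_genes)]
    rng = np.random.default_rng(seed + 3)
    true_fc = {
        (g, tp): float(np.round(rng.normal(0.0, 1.5), 3))
        for g in genes
        for tp in config.qpcr_timepoints
    }
    ct, ct_truth = sd.generate_ct_table(
        genes,
        config.qpcr_timepoints,
        true_fc,
        noise_sd=config.ct_noise_sd,
        rng_seed=seed + 4,
    )
    ct.to_csv(out / "ct_table.csv", index=False)
    ct_truth.to_csv(out / "ct_truth.csv", index=False)

    bundle.artifacts.update(
        {
            "seed_profile": out / "seed_profile.txt",
            "proteome": out / "proteome.fasta",
            "proteome_truth": out / "proteome_truth.tsv",
            "genome": out / "genome.fasta",
            "gff": out / "genome.gff3",
            "genome_truth": out / "genome_truth.tsv",
            "genome_cds": out / "genome_cds.fasta",
            "expression_matrix": out / "expression_matrix.tsv",
            "ct_table": out / "ct_table.csv",
        }
    )
    # hold generated objects in memory for downstream stages in the same run
    bundle.log.setdefault("objects", {}).update(
        {"genome_bundle": genome, "profile": profile}
    )


def stage_identify(config: PipelineConfig, bundle: ReportBundle) -> None:
    out = bundle.out_dir
    proteome = tio.read_fasta(_require(bundle, "proteome", "identify"))
    profile = ds.load_profile(_require(bundle, "seed_profile", "identify"))
    search = ds.SearchConfig(
        e_threshold=config.e_threshold,
        min_model_coverage=config.min_model_coverage,
        n_calibration_shuffles=config.n_calibration_shuffles,
        pass1_e_threshold=config.pass1_e_threshold,
        rng_seed=config.stage_seed("identify"),
    )
    hits, species_profile = ds.two_pass_identify(profile, proteome, search)
    rows = [
        {
            "sequence_id": h.sequence_id,
            "score_bits": round(h.score, 3),
            "e_value": h.e_value,
            "seq_start": h.seq_start,
            "seq_end": h.seq_end,
            "model_start": h.model_start,
            "model_end": h.model_end,
            "model_coverage": round(h.model_coverage, 4),
        }
        for h in hits
    ]
    pd.DataFrame(rows).to_csv(out / "hits.tsv", sep="\t", index=False)
    ds.save_profile(species_profile, out / "species_profile.txt")
    segments = {h.sequence_id: h.model_aligned for h in hits}
    tio.write_fasta(segments, out / "hit_segments.fasta")
    bundle.artifacts.update(
        {
            "hits": out / "hits.tsv",
            "species_profile": out / "species_profile.txt",
            "hit_segments": out / "hit_segments.fasta",
        }
    )


def stage_catalog(config: PipelineConfig, bundle: ReportBundle) -> None:
    out = bundle.out_dir
    genome = bundle.log.get("objects", {}).get("genome_bundle")
    if genome is None:
        raise PipelineError("stage 'catalog' requires artifact 'genome_bundle'; run simulate first")
    table = cat.catalog_from_genes(genome.genes)
    table.to_csv(out / "catalog.tsv", sep="\t", index=False)
    summary = cat.summarize_catalog(table)
    (out / "catalog_summary.yaml").write_text(yaml.safe_dump(summary, sort_keys=True))
    bundle.artifacts.update(
        {"catalog": out / "catalog.tsv", "catalog_summary": out / "catalog_summary.yaml"}
    )


def stage_duplications(config: PipelineConfig, bundle: ReportBundle) -> None:
    out = bundle.out_dir
    genome = bundle.log.get("objects", {}).get("genome_bundle")
    if genome is None:
        raise PipelineError("stage 'duplications' requires artifact 'genome_bundle'; run simulate first")
    proteins = {
        g.gene_id: str(Seq(g.cds).translate()).rstrip("*") for g in genome.genes
    }
    loci = {
        g.gene_id: dup.GeneLocus(g.gene_id, g.chromosome, g.exons[0][0], g.exons[-1][1])
        for g in genome.genes
    }
    family_ids = set(genome.truth[genome.truth.is_family].index)

    anchors = dup.find_anchor_pairs(
        proteins,
        proteins,
        loci,
        top_k=config.anchor_top_k,
        score_threshold=config.anchor_score_threshold,
    )
    blocks = dup.chain_collinear_blocks(
        anchors, min_anchors=config.min_anchors, max_gap=config.collinearity_max_gap
    )
    tandem = dup.find_tandem_events(
        [loci[i] for i in sorted(family_ids)], window=config.tandem_window
    )
    events = dup.classify_family_duplications(blocks, tandem, family_ids)

    pd.DataFrame(
        [
            {
                "gene_a": a.gene_a,
                "gene_b": a.gene_b,
                "score": a.score,
                "chrom_a": a.chrom_a,
                "chrom_b": a.chrom_b,
                "rank_a": a.rank_a,
                "rank_b": a.rank_b,
            }
            for a in anchors
        ]
    ).to_csv(out / "anchors.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "block_id": i,
                "chrom_a": b.chromosomes[0],
                "chrom_b": b.chromosomes[1],
                "orientation": b.orientation,
                "n_anchors": len(b.anchors),
                "score": b.score,
                "anchors": ";".join(f"{a.gene_a}|{a.gene_b}" for a in b.anchors),
            }
            for i, b in enumerate(blocks)
        ]
    ).to_csv(out / "blocks.tsv", sep="\t", index=False)

    cds = {g.gene_id: g.cds for g in genome.genes}
    kaks_rows = []
    for e in events:
        aligned_a, aligned_b = dup.align_codon_pair(cds[e.gene_a], cds[e.gene_b])
        result = dup.kaks_ng86(aligned_a, aligned_b)
        kaks_rows.append(
            {
                "gene_a": e.gene_a,
                "gene_b": e.gene_b,
                "kind": e.kind,
                "ka": round(result.ka, 4),
                "ks": round(result.ks, 4),
                "ka_ks": None if result.ratio is None else round(result.ratio, 4),
                "saturated": result.saturated,
            }
        )
    pd.DataFrame(
        kaks_rows, columns=["gene_a", "gene_b", "kind", "ka", "ks", "ka_ks", "saturated"]
    ).to_csv(out / "duplication_events.tsv", sep="\t", index=False)
    bundle.artifacts.update(
        {
            "anchors": out / "anchors.tsv",
            "blocks": out / "blocks.tsv",
            "events": out / "duplication_events.tsv",
        }
    )


def stage_phylogeny(config: PipelineConfig, bundle: ReportBundle) -> None:
    out = bundle.out_dir
    segments = tio.read_alignment_fasta(_require(bundle, "hit_segments", "phylogeny"))
    truth = pd.read_csv(
        _require(bundle, "proteome_truth", "phylogeny"), sep="\t", index_col=0
    )
    if len(segments) < 4:
        raise PipelineError("phylogeny needs at least 4 identified sequences")
    tree = ph.bootstrap_support(
        segments,
        replicates=config.bootstrap_replicates,
        rng_seed=config.stage_seed("phylogeny"),
    )
    # markers: the first identified member of each true subfamily, standing in
    # for previously classified genes from the literature
    markers: dict[str, str] = {}
    for name in sorted(segments):
        subfam = truth.loc[name, "subfamily"] if name in truth.index else None
        if isinstance(subfam, str) and subfam not in markers.values():
            markers[name] = subfam
    assignment = ph.assign_subfamilies(tree, markers)
    ph.write_newick(tree, out / "tree.nwk")
    pd.DataFrame(
        [
            {
                "gene_id": g,
                "subfamily": assignment.labels[g],
                "markers": ";".join(assignment.supporting_markers.get(g, ())),
                "ambiguous": g in assignment.ambiguous,
            }
            for g in sorted(assignment.labels)
        ]
    ).to_csv(out / "subfamily_assignments.tsv", sep="\t", index=False)
    bundle.artifacts.update(
        {"tree": out / "tree.nwk", "assignments": out / "subfamily_assignments.tsv"}
    )


def stage_elements(config: PipelineConfig, bundle: ReportBundle) -> None:
    out = bundle.out_dir
    genome = bundle.log.get("objects", {}).get("genome_bundle")
    if genome is None:
        raise PipelineError("stage 'elements' requires artifact 'genome_bundle'; run simulate first")
    family_genes = [
        g for g in genome.genes if bool(genome.truth.loc[g.gene_id, "is_family"])
    ]
    promoters = me.extract_promoters(
        genome.chromosomes, family_genes, length=config.promoter_length
    )
    library = me.load_element_library()
    matches = me.scan_promoters(promoters, library)
    shared = me.shared_elements(promoters, library)
    matches.to_csv(out / "element_matches.tsv", sep="\t", index=False)
    (out / "shared_elements.txt").write_text("\n".join(sorted(shared)) + "\n")
    bundle.artifacts.update(
        {
            "element_matches": out / "element_matches.tsv",
            "shared_elements": out / "shared_elements.txt",
        }
    )


def stage_expression(config: PipelineConfig, bundle: ReportBundle) -> None:
    out = bundle.out_dir
    matrix = pd.read_csv(
        _require(bundle, "expression_matrix", "expression"), sep="\t", index_col=0
    )
    bins = ex.bin_matrix(matrix)
    groups, _ = ex.cluster_genes(matrix, k=config.expression_groups)
    bins.to_csv(out / "expression_bins.tsv", sep="\t")
    groups.to_frame().to_csv(out / "expression_groups.tsv", sep="\t")

    ct = ex.read_ct_table(_require(bundle, "ct_table", "expression"))
    result = ex.FoldChangeResult.from_ct(ct, baseline="t0")
    result.table.to_csv(out / "fold_changes.tsv", sep="\t", index=False)
    bundle.artifacts.update(
        {
            "expression_bins": out / "expression_bins.tsv",
            "expression_groups": out / "expression_groups.tsv",
            "fold_changes": out / "fold_changes.tsv",
        }
    )


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "identify": stage_identify,
    "catalog": stage_catalog,
    "duplications": stage_duplications,
    "phylogeny": stage_phylogeny,
    "elements": stage_elements,
    "expression": stage_expression,
}


def run_pipeline(config: PipelineConfig, out_dir) -> ReportBundle:
    """Run the enabled stages in dependency order and write a run log."""
    unknown = [s for s in config.stages if s not in STAGES]
    if unknown:
        raise ValidationError(f"unknown stages: {unknown}")
    out = tio.ensure_dir(out_dir)
    bundle = ReportBundle(out_dir=out)
    for stage in STAGES:
        if stage in config.stages:
            _STAGE_FUNCS[stage](config, bundle)
    log = {
        "package_version": trihelix.__version__,
        "rng_seed": config.rng_seed,
        "stage_seeds": {s: config.stage_seed(s) for s in config.stages},
        "parameters": yaml.safe_load(dump_config(config)),
        "artifacts": {k: str(v) for k, v in bundle.artifacts.items()},
    }
    (out / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=True))
    bundle.artifacts["run_log"] = out / "run_log.yaml"
    bundle.log["run"] = log
    return bundle
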