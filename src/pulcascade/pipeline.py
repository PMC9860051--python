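"""End-to-end orchestration: simulate -> annotate -> mine -> compare, plus
the proteomics and array stages, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

from . import __version__, annotation, arrays, comparative, io, mining, proteomics, synthetic
from .config import RunConfig, validate_config

log = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the configured stages into ``outdir``; returns the manifest.

    Fails fast on an invalid config. The manifest records the configuration,
    package version, per-file SHA-256 hashes and a timestamp; two runs with
    the same (config, seed) produce identical manifests modulo the
    timestamp.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(config.stages)
    written: list = []

    def emit(name):
        written.append(outdir / name)
        return outdir / name

    truth = genes = annotations = puls = None
    matrix = meta = spots = None

    if "simulate" in stages:
        g = config.genome
        truth = synthetic.generate_genome(
            n_contigs=g.n_contigs,
            n_genes_per_contig=g.n_genes_per_contig,
            n_puls=g.n_puls,
            n_decoys=g.n_decoys,
            seed=config.seed,
        )
        noise = synthetic.NoiseConfig(
            fp_rate=g.fp_rate,
            fn_rate=g.fn_rate,
            near_threshold_fraction=g.near_threshold_fraction,
            seed=config.seed + 1,
        )
        domain, search, intents = synthetic.generate_hit_tables(truth, noise)
        genes = truth.genes
        io.write_gene_table(genes, emit("genes.tsv"))
        io.write_gff3(genes, emit("genes.gff3"))
        io.write_domtbl(domain, emit("domain_hits.domtbl"))
        io.write_search_table(search, emit("search_hits.tsv"))
        io.write_truth(truth, emit("truth.json"))
        log.info("simulate: %d genes, %d planted loci", len(genes), len(truth.planted_puls))
        if "proteomics" in stages:
            ps = config.proteome
            matrix, meta, ptruth = synthetic.generate_proteome(
                n_proteins=ps.n_proteins,
                conditions=tuple(ps.conditions),
                n_reps=ps.n_reps,
                effect_proteins=ps.effect_proteins,
                effect_fold=ps.effect_fold,
                cv=ps.cv,
                missing_rate=ps.missing_rate,
                seed=config.seed + 2,
            )
            io.write_intensity(matrix, meta, emit("ibaq.tsv"), emit("samples.tsv"))
            ptruth.to_csv(emit("proteome_truth.tsv"), sep="\t")
        if "arrays" in stages:
            a = config.arrays_sim
            spots, atruth = synthetic.generate_arrays(
                n_extracts=a.n_extracts,
                n_probes=a.n_probes,
                treatments=tuple(a.treatments),
                deletion_depth=a.deletion_depth,
                n_spots=a.n_spots,
                noise_cv=a.noise_cv,
                seed=config.seed + 3,
            )
            io.write_spots(spots, emit("spots.tsv"))
            atruth.to_csv(emit("array_truth.tsv"), sep="\t", index=False)

    if "annotate" in stages:
        if genes is None:
            raise ValueError("annotate stage needs the simulate stage (or use the CLI on files)")
        domain = io.read_domtbl(outdir / "domain_hits.domtbl")
        search = io.read_search_table(outdir / "search_hits.tsv")
        annotations = annotation.annotate_genome(
            genes, domain, search, mode=config.annotate.mode
        )
        io.write_annotations(annotations, emit("annotations.tsv"))

    if "mine" in stages:
        if annotations is None:
            raise ValueError("mine stage needs annotations")
        params = mining.MineParams(
            frame=config.mine.frame,
            max_gap=config.mine.max_gap,
            require_same_strand=config.mine.require_same_strand,
            window_mode=config.mine.window_mode,
        )
        puls = mining.mine_assembly(genes, annotations, params)
        io.write_puls(puls, emit("puls.tsv"))
        io.write_puls_json(puls, emit("puls.json"))
        log.info("mine: %d loci", len(puls))

    if "compare" in stages and puls:
        reference = comparative.ReferenceModule()
        frame = io.puls_to_frame(puls)
        frame["same_modularity"] = [
            comparative.same_modularity(p, reference) for p in puls
        ]
        frame.to_csv(emit("modularity.tsv"), sep="\t", index=False)
        comparative.cooccurrence(puls).to_csv(
            emit("cooccurrence.tsv"), sep="\t", index=False
        )
        comparative.intersection_counts(puls).to_csv(
            emit("intersections.tsv"), sep="\t", index=False
        )
        if annotations is not None:
            match = comparative.mag_repertoire_match(annotations, reference)
            (outdir / "mag_match.json").write_text(
                json.dumps(match, indent=1, sort_keys=True)
            )
            written.append(outdir / "mag_match.json")

    if "proteomics" in stages and matrix is not None:
        ribaq = proteomics.compute_ribaq(matrix)
        kept = proteomics.detection_filter(matrix, meta)
        conds = list(dict.fromkeys(meta["condition"]))
        reference = config.proteomics.reference
        other = next(c for c in conds if c != reference)
        results = proteomics.permutation_fdr(
            ribaq.loc[kept],
            meta,
            conditions=(reference, other),
            alpha=config.proteomics.alpha,
            n_perm=config.proteomics.n_perm,
            seed=config.seed + 4,
            s0=config.proteomics.s0,
        )
        results.to_csv(emit("proteomics_results.tsv"), sep="\t")
        proteomics.fold_changes(ribaq.loc[kept], meta, reference).to_csv(
            emit("fold_changes.tsv"), sep="\t", index=False
        )
        log.info("proteomics: %d significant proteins", int(results["significant"].sum()))

    if "arrays" in stages and spots is not None:
        means, flagged = arrays.mean_replicates(spots)
        normalized = arrays.normalize_dataset(means)
        scores = arrays.epitope_deletion_score(
            normalized, config.arrays.treatment, config.arrays.control
        )
        scores.to_csv(emit("epitope_scores.tsv"), sep="\t", index=False)
        if not flagged.empty:
            flagged.to_csv(emit("flagged_cells.tsv"), sep="\t", index=False)

    manifest = {
        "pulcascade_version": __version__,
        "config": config.to_dict(),
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
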