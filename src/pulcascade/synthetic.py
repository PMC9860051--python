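"""Seeded synthetic inputs with known ground truth for every pipeline stage.

The genome generator plants loci with the *Muricauda*-type beta-mannan PUL
architecture (SusC/D pair, three GH26 mannanases, GH5, GH27, GH130, CE2,
plus unannotated regulator/transporter genes) among background genes and
decoy clusters, on a fixed 1 kb coordinate grid — only gene order matters
downstream. Hit-table generators emit HMM-domain and sequence-search
evidence whose pass/fail intent against the annotation thresholds is
recorded, with controllable false-positive/negative rates and
near-threshold scores. Proteome and array generators plant condition
effects and epitope deletions under lognormal replicate noise.

Everything is driven by ``numpy.random.default_rng`` seeds: identical
(config, seed) give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import SUSD_PROFILES, ConfirmRules, FilterRules
from .core import GT, NONE, SUSC, SUSD, Gene, is_cazyme_label

#: Reference planting architecture (gene order along the locus). ``NONE``
#: entries stand for the regulator/transporter genes that carry no CAZyme or
#: SusC/D annotation.
DEFAULT_ARCHITECTURE = (
    "GH26",
    "GH130",
    "NONE",
    "SUSC",
    "SUSD",
    "GH26",
    "GH26",
    "GH5",
    "GH27",
    "NONE",
    "CE2",
)

#: Families used for spurious hits and decoy CAZyme runs (seen co-occurring
#: with GH26 clusters in real screens).
DECOY_FAMILIES = ("GH10", "GH95", "GH97", "GH16", "GH3", "CE6", "PL7")

_SUSD_PROFILE_VERSIONS = {
    "PF12741": "PF12741.10",
    "PF12771": "PF12771.10",
    "PF14322": "PF14322.9",
    "PF07980": "PF07980.14",
}

#: Profile length assumed when writing HMMER coordinates; coverages are
#: quantized to this grid so tables round-trip exactly.
PROFILE_LENGTH = 300

GENE_LENGTH = 900
GENE_GRID = 1000


class CapacityError(ValueError):
    """Requested features cannot be placed disjointly on the contigs."""


@dataclass(frozen=True)
class NoiseConfig:
    """Noise model for hit-table generation.

    fp_rate: probability of a spurious hit per unlabeled protein.
    fn_rate: probability of dropping each true hit.
    near_threshold_fraction: fraction of scores placed within one order of
    magnitude of the filtering thresholds (on the intended side).
    """

    fp_rate: float = 0.0
    fn_rate: float = 0.0
    near_threshold_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("fp_rate", "fn_rate", "near_threshold_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class PlantedPUL:
    contig_id: str
    start_index: int  # order index of the first terminus-eligible gene
    end_index: int
    architecture: str


@dataclass
class GenomeTruth:
    """A synthetic assembly with its ground truth."""

    genes: list
    true_labels: dict  # gene_id -> family | SUSC | SUSD | GT | NONE
    profiles: dict  # gene_id -> profile/family name used for hit generation
    planted_puls: list = field(default_factory=list)


def _as_label(entry: str) -> str:
    if entry in (SUSC, SUSD, NONE):
        return entry
    if entry.startswith("GT"):
        return GT
    return entry


def _terminus_eligible(entry: str) -> bool:
    label = _as_label(entry)
    return label in (SUSC, SUSD) or is_cazyme_label(label)


def _validate_architecture(architecture) -> None:
    labels = [_as_label(e) for e in architecture]
    if labels.count(SUSC) != 1 or labels.count(SUSD) != 1:
        raise ValueError("architecture must contain exactly one SUSC and one SUSD")
    gap = abs(labels.index(SUSC) - labels.index(SUSD)) - 1
    if gap > 1:
        raise ValueError("SUSC and SUSD must be adjacent or separated by one gene")
    if not any(_terminus_eligible(e) for e in architecture):
        raise ValueError("architecture holds no terminus-eligible gene")


def _decoy_blocks(n_decoys: int, rng) -> list:
    """Three decoy kinds, cycled: (a) a lone SusC/D pair without nearby
    CAZymes, (b) a CAZyme run without a SusC/D pair, (c) a GT-only cluster
    adjacent to a SusC/D pair."""
    kinds = []
    for k in range(n_decoys):
        which = k % 3
        if which == 0:
            kinds.append(("decoy_suscd", (SUSC, SUSD)))
        elif which == 1:
            fams = tuple(rng.choice(DECOY_FAMILIES, size=3, replace=True))
            kinds.append(("decoy_cazyme_run", fams))
        else:
            kinds.append(("decoy_gt_cluster", ("GT2", "GT4", SUSC, SUSD, "GT2")))
    return kinds


def generate_genome(
    n_contigs: int = 1,
    n_genes_per_contig: int = 60,
    n_puls: int = 1,
    architecture=DEFAULT_ARCHITECTURE,
    n_decoys: int = 3,
    seed: int = 0,
    buffer_genes: int = 8,
) -> GenomeTruth:
    """Plant ``n_puls`` reference-architecture loci and ``n_decoys`` decoy
    clusters on ``n_contigs`` contigs of ``n_genes_per_contig`` genes.

    Blocks are separated by at least ``buffer_genes`` unannotated genes (one
    more than the default seven-gene frame, so planted loci never bleed into
    each other). Raises :class:`CapacityError` when the requested features
    cannot be placed disjointly.
    """
    rng = np.random.default_rng(seed)
    architecture = tuple(architecture)
    _validate_architecture(architecture)

    blocks = [("pul", architecture) for _ in range(n_puls)]
    blocks += _decoy_blocks(n_decoys, rng)
    per_contig: list = [[] for _ in range(n_contigs)]
    for i, block in enumerate(blocks):
        per_contig[i % n_contigs].append(block)

    genes: list = []
    true_labels: dict = {}
    profiles: dict = {}
    planted: list = []
    for c in range(n_contigs):
        contig = f"ctg{c + 1:02d}"
        cblocks = per_contig[c]
        need = sum(len(b) for _, b in cblocks) + max(0, len(cblocks) - 1) * buffer_genes
        if need > n_genes_per_contig:
            raise CapacityError(
                f"{contig}: {need} gene slots needed for {len(cblocks)} blocks "
                f"but only {n_genes_per_contig} available"
            )
        spare = n_genes_per_contig - need
        n_gaps = len(cblocks) + 1
        extra = rng.multinomial(spare, np.full(n_gaps, 1.0 / n_gaps))
        layout = []  # (offset, kind, entries)
        pos = 0
        for k, (kind, entries) in enumerate(cblocks):
            pos += int(extra[k]) + (buffer_genes if k > 0 else 0)
            layout.append((pos, kind, entries))
            pos += len(entries)

        block_at = {}
        for offset, kind, entries in layout:
            for j, entry in enumerate(entries):
                block_at[offset + j] = entry
            if kind == "pul":
                eligible = [j for j, e in enumerate(entries) if _terminus_eligible(e)]
                planted.append(
                    PlantedPUL(
                        contig,
                        offset + eligible[0],
                        offset + eligible[-1],
                        "muricauda_beta_mannan",
                    )
                )

        for idx in range(n_genes_per_contig):
            entry = block_at.get(idx, NONE)
            in_block = idx in block_at
            gene_id = f"{contig}_g{idx:04d}"
            genes.append(
                Gene(
                    contig_id=contig,
                    order_index=idx,
                    gene_id=gene_id,
                    start=idx * GENE_GRID + 1,
                    end=idx * GENE_GRID + GENE_LENGTH,
                    strand="+" if in_block else str(rng.choice(["+", "-"])),
                    locus_tag=gene_id,
                )
            )
            true_labels[gene_id] = _as_label(entry)
            if entry not in (NONE,):
                profiles[gene_id] = entry
    return GenomeTruth(genes, true_labels, profiles, planted)


def _log10_score(rng, threshold_log10, passing, near, margin=(0.05, 1.0), far=(3.0, 25.0)):
    """A log10 e-value respecting a pass/fail intent against a threshold.

    Passing scores sit below the threshold, failing ones above; ``near``
    places the score within one decade of the threshold."""
    lo, hi = margin if near else far
    delta = rng.uniform(lo, hi)
    return threshold_log10 - delta if passing else threshold_log10 + delta


def _quantized_coverage(rng, lo=0.40, hi=0.95) -> float:
    k = rng.integers(int(lo * PROFILE_LENGTH), int(hi * PROFILE_LENGTH) + 1)
    return k / PROFILE_LENGTH


def _susd_profile(rng) -> str:
    name = sorted(SUSD_PROFILES)[rng.integers(len(SUSD_PROFILES))]
    return _SUSD_PROFILE_VERSIONS[name]


def generate_hit_tables(
    truth: GenomeTruth,
    noise: NoiseConfig = NoiseConfig(),
    filter_rules: FilterRules = FilterRules(),
    confirm_rules: ConfirmRules = ConfirmRules(),
):
    """Domain-hit and search-hit tables for a synthetic assembly.

    Every labeled protein yields a passing hit in each relevant table with
    probability 1 - fn_rate; unlabeled proteins gain spurious hits at
    fp_rate. Spurious domain hits may pass the HMM filter yet lack (or fail)
    search confirmation, exercising the dual-evidence rejection path. Hit
    fields are generated consistent with their pass/fail intent, which is
    recorded in the returned intent table.

    Returns ``(domain_hits, search_hits, intents)`` DataFrames.
    """
    rng = np.random.default_rng(noise.seed)
    e_hmm = np.log10(filter_rules.e_value_long)
    e_search = np.log10(confirm_rules.max_e_value)
    domain_rows: list = []
    search_rows: list = []
    intents: list = []

    def add_domain(pid, profile, passing, near):
        aln = int(rng.integers(100, 301))
        start = int(rng.integers(1, 21))
        domain_rows.append(
            {
                "protein_id": pid,
                "profile_name": profile,
                "e_value": 10.0 ** _log10_score(rng, e_hmm, passing, near),
                "alignment_length": aln,
                # pass/fail intent is carried by the e-value; coverage passes
                "profile_coverage": _quantized_coverage(rng),
                "env_start": start,
                "env_end": start + aln - 1,
            }
        )
        intents.append(
            {"protein_id": pid, "stage": "hmm", "name": profile, "intended_pass": passing}
        )

    def add_search(pid, family, passing, near):
        search_rows.append(
            {
                "query_id": pid,
                "subject_id": f"db|{family}|{rng.integers(1000, 9999)}",
                "subject_family": family,
                "percent_identity": round(float(rng.uniform(35, 90)), 1),
                "query_coverage": round(float(rng.uniform(45, 95)), 1),
                "e_value": 10.0 ** _log10_score(rng, e_search, passing, near),
            }
        )
        intents.append(
            {"protein_id": pid, "stage": "search", "name": family, "intended_pass": passing}
        )

    def near_roll() -> bool:
        return bool(rng.random() < noise.near_threshold_fraction)

    for gene in truth.genes:
        pid = gene.gene_id
        label = truth.true_labels[pid]
        profile = truth.profiles.get(pid)
        if label == NONE:
            if rng.random() < noise.fp_rate:
                family = str(rng.choice(DECOY_FAMILIES))
                hmm_pass = bool(rng.random() < 0.7)
                add_domain(pid, family, hmm_pass, near_roll())
                if hmm_pass:
                    roll = rng.random()
                    if roll < 0.5:
                        add_search(pid, family, True, near_roll())
                    elif roll < 0.75:
                        add_search(pid, family, False, True)
            continue
        if label in (SUSC, SUSD):
            if rng.random() >= noise.fn_rate:
                name = "TIGR04056" if label == SUSC else _susd_profile(rng)
                add_domain(pid, name, True, near_roll())
            continue
        # CAZy family (including GT families)
        if rng.random() >= noise.fn_rate:
            add_domain(pid, profile, True, near_roll())
        if rng.random() >= noise.fn_rate:
            add_search(pid, profile, True, near_roll())

    domain = pd.DataFrame(
        domain_rows,
        columns=[
            "protein_id",
            "profile_name",
            "e_value",
            "alignment_length",
            "profile_coverage",
            "env_start",
            "env_end",
        ],
    )
    search = pd.DataFrame(
        search_rows,
        columns=[
            "query_id",
            "subject_id",
            "subject_family",
            "percent_identity",
            "query_coverage",
            "e_value",
        ],
    )
    intent = pd.DataFrame(
        intents, columns=["protein_id", "stage", "name", "intended_pass"]
    )
    return domain, search, intent


def check_hit_consistency(
    domain: pd.DataFrame,
    search: pd.DataFrame,
    intents: pd.DataFrame,
    filter_rules: FilterRules = FilterRules(),
    confirm_rules: ConfirmRules = ConfirmRules(),
) -> bool:
    """Verify that generated hit fields satisfy their recorded intent."""
    for _, row in intents[intents["stage"] == "hmm"].iterrows():
        hit = domain[
            (domain["protein_id"] == row["protein_id"])
            & (domain["profile_name"] == row["name"])
        ].iloc[0]
        threshold = (
            filter_rules.e_value_long
            if hit["alignment_length"] > filter_rules.long_alignment
            else filter_rules.e_value_short
        )
        passes = (
            hit["e_value"] < threshold
            and hit["profile_coverage"] > filter_rules.min_coverage
        )
        if passes != row["intended_pass"]:
            return False
    for _, row in intents[intents["stage"] == "search"].iterrows():
        hit = search[
            (search["query_id"] == row["protein_id"])
            & (search["subject_family"] == row["name"])
        ].iloc[0]
        passes = (
            hit["e_value"] <= confirm_rules.max_e_value
            and hit["query_coverage"] >= confirm_rules.min_query_coverage
            and hit["percent_identity"] >= confirm_rules.min_identity
        )
        if passes != row["intended_pass"]:
            return False
    return True


def generate_proteome(
    n_proteins: int = 1000,
    conditions=("galactomannan", "pectin", "mannose"),
    n_reps: int = 3,
    effect_proteins=22,
    effect_fold: float = 8.0,
    cv: float = 0.2,
    missing_rate: float = 0.0,
    seed: int = 0,
):
    """Lognormal iBAQ matrix with planted condition effects.

    Effect proteins (an id iterable, or a count drawn at random) are
    multiplied by ``effect_fold`` in the first condition. ``cv`` is the
    per-measurement coefficient of variation; missingness is uniform at
    random per cell. With ``effect_fold=1`` no protein is flagged as a true
    positive.

    Returns ``(matrix, meta, truth)``: protein x sample intensities, sample
    metadata (condition, replicate), and per-protein truth flags.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if effect_fold <= 0:
        raise ValueError("effect_fold must be > 0")
    if not 0 <= missing_rate <= 1:
        raise ValueError("missing_rate must be in [0, 1]")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    ids = [f"P{i + 1:05d}" for i in range(n_proteins)]
    if isinstance(effect_proteins, (int, np.integer)):
        if effect_proteins > n_proteins:
            raise ValueError("more effect proteins than proteins")
        chosen = rng.choice(n_proteins, size=int(effect_proteins), replace=False)
        effect_ids = {ids[i] for i in chosen}
    else:
        effect_ids = set(effect_proteins)
        unknown = effect_ids - set(ids)
        if unknown:
            raise ValueError(f"unknown effect proteins: {sorted(unknown)}")
    base = 10.0 ** rng.normal(7.0, 1.0, size=n_proteins)
    sigma = np.sqrt(np.log1p(cv**2))
    samples = [f"{c}_r{r + 1}" for c in conditions for r in range(n_reps)]
    meta = pd.DataFrame(
        {
            "condition": [c for c in conditions for _ in range(n_reps)],
            "replicate": [r + 1 for _ in conditions for r in range(n_reps)],
        },
        index=pd.Index(samples, name="sample"),
    )
    effect_mask = np.array([i in effect_ids for i in ids])
    values = np.empty((n_proteins, len(samples)))
    for j, sample in enumerate(samples):
        fold = np.where(
            effect_mask & (meta.loc[sample, "condition"] == conditions[0]),
            effect_fold,
            1.0,
        )
        noise = np.exp(rng.normal(0.0, sigma, size=n_proteins)) if sigma > 0 else 1.0
        values[:, j] = base * fold * noise
    if missing_rate > 0:
        values[rng.random(values.shape) < missing_rate] = np.nan
    matrix = pd.DataFrame(values, index=pd.Index(ids, name="protein_id"), columns=samples)
    truth = pd.DataFrame(
        {"effect": effect_mask & (effect_fold != 1.0)},
        index=pd.Index(ids, name="protein_id"),
    )
    return matrix, meta, truth


def generate_arrays(
    n_extracts: int = 4,
    n_probes: int = 2,
    treatments=("GH26C", "buffer"),
    deletion_targets=None,
    deletion_depth: float = 1.0,
    n_spots: int = 2,
    noise_cv: float = 0.0,
    seed: int = 0,
    control: str = "buffer",
):
    """Replicate-spotted array signals with planted epitope deletions.

    ``deletion_targets`` is a set of (extract, probe, treatment) cells whose
    base signal is multiplied by (1 - deletion_depth) before replicate noise
    is applied; the buffer control never carries deletions. Defaults to
    deleting the first probe of every extract under the first non-control
    treatment. ``noise_cv=0`` gives the noise-free mode.

    Returns ``(spots, truth)`` DataFrames.
    """
    if n_spots < 2:
        raise ValueError("n_spots must be >= 2 (replicate invariant)")
    if not 0 <= deletion_depth <= 1:
        raise ValueError("deletion_depth must be in [0, 1]")
    if control not in treatments:
        raise ValueError(f"control treatment {control!r} missing from treatments")
    rng = np.random.default_rng(seed)
    extracts = [f"extract{e + 1:02d}" for e in range(n_extracts)]
    probes = [f"probe{p + 1:02d}" for p in range(n_probes)]
    if deletion_targets is None:
        treated = next(t for t in treatments if t != control)
        deletion_targets = {(e, probes[0], treated) for e in extracts}
    deletion_targets = set(deletion_targets)
    for e, p, t in deletion_targets:
        if t == control:
            raise ValueError("deletion targets must not name the control treatment")
        if e not in extracts or p not in probes or t not in treatments:
            raise ValueError(f"unknown deletion target {(e, p, t)}")
    sigma = np.sqrt(np.log1p(noise_cv**2))
    base = {
        (e, p): float(rng.uniform(20.0, 100.0)) for e in extracts for p in probes
    }
    rows = []
    for t in treatments:
        for e in extracts:
            for p in probes:
                level = base[(e, p)]
                if (e, p, t) in deletion_targets:
                    level *= 1.0 - deletion_depth
                for r in range(n_spots):
                    noise = float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0
                    rows.append(
                        {
                            "extract_id": e,
                            "probe_id": p,
                            "treatment": t,
                            "replicate": r + 1,
                            "signal": level * noise,
                        }
                    )
    spots = pd.DataFrame(rows)
    truth = pd.DataFrame(
        [
            {"extract_id": e, "probe_id": p, "treatment": t, "depth": deletion_depth}
            for e, p, t in sorted(deletion_targets)
        ],
        columns=["extract_id", "probe_id", "treatment", "depth"],
    )
    return spots, truth
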