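"""Run configuration: one hierarchical document driving every stage.

A :class:`RunConfig` serializes losslessly to/from YAML; every stochastic
stage derives its seed from the single top-level seed, so a (config, seed)
pair fixes the whole run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class GenomeSimConfig:
    n_contigs: int = 2
    n_genes_per_contig: int = 60
    n_puls: int = 2
    n_decoys: int = 3
    fp_rate: float = 0.0
    fn_rate: float = 0.0
    near_threshold_fraction: float = 0.0


@dataclass
class ProteomeSimConfig:
    n_proteins: int = 300
    conditions: list = field(
        default_factory=lambda: ["galactomannan", "pectin", "mannose"]
    )
    n_reps: int = 3
    effect_proteins: int = 22
    effect_fold: float = 8.0
    cv: float = 0.2
    missing_rate: float = 0.0


@dataclass
class ArraySimConfig:
    n_extracts: int = 4
    n_probes: int = 2
    treatments: list = field(default_factory=lambda: ["GH26C", "buffer"])
    deletion_depth: float = 1.0
    n_spots: int = 2
    noise_cv: float = 0.0


@dataclass
class AnnotateConfig:
    mode: str = "confirmed"  # 'confirmed' | 'hmm-only'


@dataclass
class MineConfig:
    frame: int = 7
    max_gap: int = 1
    require_same_strand: bool = True
    window_mode: str = "iterative"


@dataclass
class ProteomicsConfig:
    reference: str = "galactomannan"
    alpha: float = 0.05
    n_perm: int = 250
    s0: str = "median"


@dataclass
class ArraysConfig:
    control: str = "buffer"
    treatment: str = "GH26C"


DEFAULT_STAGES = ["simulate", "annotate", "mine", "compare", "proteomics", "arrays"]


@dataclass
class RunConfig:
    stages: list = field(default_factory=lambda: list(DEFAULT_STAGES))
    seed: int = 0
    genome: GenomeSimConfig = field(default_factory=GenomeSimConfig)
    proteome: ProteomeSimConfig = field(default_factory=ProteomeSimConfig)
    arrays_sim: ArraySimConfig = field(default_factory=ArraySimConfig)
    annotate: AnnotateConfig = field(default_factory=AnnotateConfig)
    mine: MineConfig = field(default_factory=MineConfig)
    proteomics: ProteomicsConfig = field(default_factory=ProteomicsConfig)
    arrays: ArraysConfig = field(default_factory=ArraysConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        """Build a config from a (possibly partial) mapping; an empty mapping
        yields the full default configuration."""
        payload = dict(payload or {})
        kwargs = {}
        for f in fields(cls):
            if f.name not in payload:
                continue
            value = payload.pop(f.name)
            if f.name in _SECTIONS and isinstance(value, dict):
                value = _SECTIONS[f.name](**value)
            kwargs[f.name] = value
        if payload:
            raise ValueError(f"unknown config keys: {sorted(payload)}")
        return cls(**kwargs)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text) or {})


_SECTIONS = {
    "genome": GenomeSimConfig,
    "proteome": ProteomeSimConfig,
    "arrays_sim": ArraySimConfig,
    "annotate": AnnotateConfig,
    "mine": MineConfig,
    "proteomics": ProteomicsConfig,
    "arrays": ArraysConfig,
}


def validate_config(config: RunConfig) -> list:
    """Range-check a config; returns a list of error strings (empty = ok).

    Never mutates its argument.
    """
    errors = []

    def check(cond, msg):
        if not cond:
            errors.append(msg)

    for stage in config.stages:
        check(stage in DEFAULT_STAGES, f"stages: unknown stage {stage!r}")
    g = config.genome
    for name in ("fp_rate", "fn_rate", "near_threshold_fraction"):
        v = getattr(g, name)
        check(0 <= v <= 1, f"genome.{name}: {v} not in [0, 1]")
    check(g.n_contigs >= 1, "genome.n_contigs must be >= 1")
    check(g.n_genes_per_contig >= 1, "genome.n_genes_per_contig must be >= 1")
    check(g.n_puls >= 0, "genome.n_puls must be >= 0")
    check(g.n_decoys >= 0, "genome.n_decoys must be >= 0")
    m = config.mine
    check(m.frame >= 1, f"mine.frame: {m.frame} must be >= 1")
    check(m.max_gap >= 0, f"mine.max_gap: {m.max_gap} must be >= 0")
    check(
        m.window_mode in ("iterative", "fixed"),
        f"mine.window_mode: unknown {m.window_mode!r}",
    )
    check(
        config.annotate.mode in ("confirmed", "hmm-only"),
        f"annotate.mode: unknown {config.annotate.mode!r}",
    )
    p = config.proteomics
    check(0 < p.alpha <= 1, f"proteomics.alpha: {p.alpha} not in (0, 1]")
    check(p.n_perm >= 2, "proteomics.n_perm must be >= 2")
    ps = config.proteome
    check(ps.n_reps >= 2, "proteome.n_reps must be >= 2")
    check(ps.effect_fold > 0, "proteome.effect_fold must be > 0")
    check(0 <= ps.missing_rate <= 1, "proteome.missing_rate must be in [0, 1]")
    check(
        p.reference in ps.conditions,
        f"proteomics.reference {p.reference!r} not among proteome.conditions",
    )
    a = config.arrays_sim
    check(a.n_spots >= 2, "arrays_sim.n_spots must be >= 2")
    check(0 <= a.deletion_depth <= 1, "arrays_sim.deletion_depth must be in [0, 1]")
    check(
        config.arrays.control in a.treatments,
        f"arrays.control {config.arrays.control!r} not among treatments",
    )
    check(
        config.arrays.treatment in a.treatments,
        f"arrays.treatment {config.arrays.treatment!r} not among treatments",
    )
    return errors
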