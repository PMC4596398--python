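"""Pipeline configuration: every tunable threshold in one place.

Defaults correspond to 50-nt read data: the exon RPKE floor and merge gap
are both calibrated to the read length, and the junction caps reject
similarity-driven mapping artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

__all__ = ["Config", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised for contradictory or unparseable configuration."""


@dataclass
class Config:
    min_exon_rpke: float = 50.0  # RPKE floor for tiled exon fragments
    min_gene_rpke: float = 100.0  # expression floor for novel-gene calls
    merge_gap: int = 50  # nt; coverage gaps up to this are closed
    read_len: int = 50  # nt; drives short-exon inference and trimming
    max_junction_span: int = 50_000  # nt; longer junctions are dropped
    max_skip_span: int = 50_000  # nt cap for junctions skipping exons
    min_footprint: int = 140  # nt; smaller models are multimapping noise
    overlap_hi: float = 0.75  # annotation overlap >= hi -> annotated
    overlap_lo: float = 0.05  # annotation overlap < lo -> novel
    max_similarity: float = 25.0  # % genome self-similarity allowed
    density_ratio: float = 0.5  # intron/flank read-start density split rule
    min_orf_codons: int = 40  # below this, likely non-coding
    seed: int = 0

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and v < 0:
                raise ConfigError(f"{f.name} must be non-negative, got {v}")
        if not (0 < self.density_ratio <= 1):
            raise ConfigError("density_ratio must be in (0, 1]")
        if self.overlap_lo >= self.overlap_hi:
            raise ConfigError("overlap_lo must be below overlap_hi")


def load_config(path: str | Path | None) -> Config:
    """Load a flat ``key = value`` config file; missing keys keep defaults."""
    cfg = Config()
    if path is None:
        cfg.validate()
        return cfg
    valid = {f.name: f.type for f in fields(Config)}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected key = value")
            key, _, value = (x.strip() for x in line.partition("="))
            if key not in valid:
                raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
            current = getattr(cfg, key)
            try:
                setattr(cfg, key, type(current)(float(value))
                        if isinstance(current, int) else float(value))
            except ValueError as exc:
                raise ConfigError(f"{path}:{lineno}: bad value for {key}") from exc
    cfg.validate()
    return cfg
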