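"""Simulation configuration: the knobs of the synthetic study design.

The defaults emulate a two-state (proliferative vs quiescent fibroblast)
design measured on a two-channel spotted microarray and by RNA-seq, scaled
down to a toy genome so the whole pipeline runs in seconds.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters of the synthetic study.

    Every simulator is a pure function of this object (plus an explicit
    stream tag), so a fixed ``seed`` yields byte-identical outputs.

    Parameters
    ----------
    seed
        Master seed; every random stream is derived from it.
    n_chromosomes, n_transcripts
        Toy genome size. Transcripts are assigned to chromosomes round-robin.
    transcript_length_range
        (min, max) transcript length in bp; min must exceed the array probe
        length so every probe fits inside its source transcript.
    array_probe_length, n_array_probes
        ~70-mer spotted probes, as on the arrays being emulated.
    decoy_fraction
        Fraction of array probes whose sequence occurs nowhere in the genome
        and which carry no transcript IDs — these must end up unmapped.
    id_fallback_fraction
        Fraction of array probes whose sequence is scrambled (absent from the
        genome) but which keep the transcript ID of their source transcript,
        exercising the ID-based mapping fallback.
    n_genes_changed, min_abs_log2_fc
        Number of transcripts with a true expression change between states,
        each with |log2 FC| of at least ``min_abs_log2_fc`` (default log2 5,
        the fivefold regime the design targets).
    baseline_log2_mean, baseline_log2_sd
        Log2 abundance distribution shared by both states before changes.
    array_scale, array_background
        Intensity units per abundance unit, and the signal level of spots
        with no target (decoys).
    array_noise_sd
        SD of the multiplicative (natural-log scale) intensity noise.
    dye_bias_cy3, dye_bias_cy5
        Multiplicative channel gains (dye/labelling bias).
    crosstalk_alpha
        Symmetric cross-channel bleed-through proportion, in [0, 0.5).
    library_sizes
        Reads per RNA-seq replicate (two replicates per state).
    nb_dispersion
        Negative-binomial dispersion of counts (0 means Poisson).
    qpcr_slope, qpcr_intercept, qpcr_ct_noise_sd
        CT model: CT = intercept + slope * log2(abundance) + noise; the
        default slope of -1 cycle per doubling is 100 % amplification
        efficiency.
    n_qpcr_genes, n_qpcr_replicates
        qRT-PCR panel size (targets, excluding the 4 normalizers) and
        reaction replicates per gene and state.
    """

    seed: int = 17
    n_chromosomes: int = 3
    n_transcripts: int = 500
    transcript_length_range: tuple[int, int] = (300, 2000)
    array_probe_length: int = 70
    n_array_probes: int = 600
    decoy_fraction: float = 0.10
    id_fallback_fraction: float = 0.05
    n_genes_changed: int = 50
    min_abs_log2_fc: float = math.log2(5.0)
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 2.0
    array_scale: float = 1000.0
    array_background: float = 5.0
    array_noise_sd: float = 0.3
    dye_bias_cy3: float = 1.0
    dye_bias_cy5: float = 1.3
    crosstalk_alpha: float = 0.05
    library_sizes: tuple[int, ...] = (1_000_000, 1_000_000)
    nb_dispersion: float = 0.05
    qpcr_slope: float = -1.0
    qpcr_intercept: float = 35.0
    qpcr_ct_noise_sd: float = 0.2
    n_qpcr_genes: int = 20
    n_qpcr_replicates: int = 3

    def validate(self) -> None:
        """Range-check every field; raise :class:`ConfigError` on the first violation."""
        if self.n_chromosomes < 1:
            raise ConfigError("n_chromosomes must be >= 1")
        if self.n_transcripts < 1:
            raise ConfigError("n_transcripts must be >= 1")
        lo, hi = self.transcript_length_range
        if not (0 < lo <= hi):
            raise ConfigError("transcript_length_range must satisfy 0 < min <= max")
        if self.array_probe_length < 1:
            raise ConfigError("array_probe_length must be >= 1")
        if lo <= self.array_probe_length:
            raise ConfigError(
                f"array probe length ({self.array_probe_length} bp) must be shorter "
                f"than the shortest transcript ({lo} bp)"
            )
        if self.n_array_probes < 1:
            raise ConfigError("n_array_probes must be >= 1")
        if not 0.0 <= self.decoy_fraction <= 1.0:
            raise ConfigError("decoy_fraction must be in [0, 1]")
        if not 0.0 <= self.id_fallback_fraction <= 1.0:
            raise ConfigError("id_fallback_fraction must be in [0, 1]")
        if self.decoy_fraction + self.id_fallback_fraction > 1.0:
            raise ConfigError("decoy_fraction + id_fallback_fraction must be <= 1")
        if not 0 <= self.n_genes_changed <= self.n_transcripts:
            raise ConfigError("n_genes_changed must be in [0, n_transcripts]")
        if self.min_abs_log2_fc < 0:
            raise ConfigError("min_abs_log2_fc must be >= 0")
        for name in ("baseline_log2_sd", "array_noise_sd", "qpcr_ct_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.array_scale <= 0 or self.array_background <= 0:
            raise ConfigError("array_scale and array_background must be > 0")
        if self.dye_bias_cy3 <= 0 or self.dye_bias_cy5 <= 0:
            raise ConfigError("dye bias factors must be > 0")
        if not 0.0 <= self.crosstalk_alpha < 0.5:
            raise ConfigError("crosstalk_alpha must be in [0, 0.5)")
        if len(self.library_sizes) == 0 or any(s <= 0 for s in self.library_sizes):
            raise ConfigError("library_sizes must be positive")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if self.n_qpcr_genes < 0 or self.n_qpcr_replicates < 1:
            raise ConfigError("qPCR panel sizes must be positive")

    # -- counts derived from fractions (fixed, not stochastic) ------------
    @property
    def n_decoy_probes(self) -> int:
        return round(self.decoy_fraction * self.n_array_probes)

    @property
    def n_id_fallback_probes(self) -> int:
        return round(self.id_fallback_fraction * self.n_array_probes)

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced (and re-validated)."""
        cfg = replace(self, **kwargs)
        cfg.validate()
        return cfg


_TUPLE_FIELDS = {"transcript_length_range", "library_sizes"}


def write_config(config: SimulationConfig, path: str | Path) -> None:
    """Write the configuration as a flat ``key=value`` text file."""
    lines = []
    for f in fields(config):
        v = getattr(config, f.name)
        if f.name in _TUPLE_FIELDS:
            v = ",".join(str(x) for x in v)
        lines.append(f"{f.name}={v}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> SimulationConfig:
    """Parse a flat ``key=value`` file; unknown keys are errors."""
    known = {f.name: f for f in fields(SimulationConfig)}
    kwargs = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected key=value, got {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in known:
            raise ConfigError(f"line {lineno}: unknown key {key!r}")
        if key in _TUPLE_FIELDS:
            kwargs[key] = tuple(int(x) for x in value.split(","))
        elif known[key].type in ("int", int):
            kwargs[key] = int(value)
        else:
            kwargs[key] = float(value)
    cfg = SimulationConfig(**kwargs)
    cfg.validate()
    return cfg


def validate_config(path: str | Path) -> list[str]:
    """Validate a config file; return a list of diagnostics (empty if valid)."""
    try:
        read_config(path)
    except (ConfigError, ValueError, OSError) as exc:
        return [str(exc)]
    return []
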