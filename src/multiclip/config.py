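"""Run configuration: every tunable of every stage, with defaults.

The file format is flat key-value text with one section per stage
(INI-style). Unknown sections or keys are an error, so typos cannot
silently fall back to defaults. Values round-trip losslessly because each
key has a fixed Python type taken from the defaults table.
"""

from __future__ import annotations

import configparser
import copy
import io as _io
import logging
from dataclasses import dataclass, field
from typing import Any

logger = logging.getLogger("multiclip")

# Defaults per stage. Values mirror the published analysis where the
# procedure states one (cutoffs, window sizes, offsets); simulation keys are
# the generator's study conditions.
_DEFAULTS: dict[str, dict[str, Any]] = {
    "global": {
        "seed": 1,
        "alphabet": "T",
    },
    "simulate": {
        "n_genes": 300,
        "frac_membrane": 0.35,
        "frac_cytosolic": 0.5,
        "frac_undefined": 0.15,
        "motifs": "UUCU,CUUC,UCUU,CUCU",
        "hotspot_motifs_min": 2,
        "hotspot_motifs_max": 4,
        "hotspots_per_membrane_cds_kb": 4.0,
        "cytosolic_motifs_per_kb": 1.0,
        "depth": 50.0,
        "conv_rate": 0.3,
        "err_rate": 0.001,
        "n_replicates": 2,
        "lib_size": 2000000,
        "dispersion": 0.05,
        "enrich_membrane": 2.5,
        "enrich_cytosolic": -1.0,
        "enrich_sd": 0.3,
        "pause_len_codons": 10,
        "pause_mult_wt": 2.0,
        "pause_mult_ko": 1.2,
        "ko_dwell_codons": "CUU,CUC,UUC,UUU",
        "ko_dwell_mult": 1.3,
        "ribo_replicates": 2,
        "trna_excess": 3.0,
        "bioid_n_true": 20,
        "bioid_true_ratio": 8.0,
        "silac_requant_frac": 0.1,
    },
    "crosslink": {
        "min_overlap": 0.5,
        "reciprocal_overlap": True,
        "max_peak_dist": 10,
        "min_mean_tc": 3.0,
        "max_specificity": 0.95,
        "min_tcpm": 5.0,
        "bins_utr5": 100,
        "bins_cds": 300,
        "bins_utr3": 200,
        "group_low": 0.3,
        "group_high": 1.39,
        "ratio_pseudocount": 0.5,
        "group_pseudocount": 0.5,
        "kept_cluster_coords": "rep1",
    },
    "classify": {
        "hi": 1.5,
        "lo": 0.5,
        "min_tpm": 10.0,
        "pseudocount": 1.0,
        "tail_anchor_max_dist": 50,
    },
    "kmer": {
        "k": 4,
        "count_mode": "overlap",
        "half_window": 40,
        "exclusion": 4,
        "n_bins": 5,
        "sliding_window": 30,
        "sliding_min_count": 3,
        "top_n_fourmers": 10,
        "top_n_zscore": 40,
    },
    "ribo": {
        "psite_offset": 13,
        "min_codon_cov": 5.0,
        "trim_codons": 2,
        "roll_start_stop": 10,
        "roll_signal": 5,
        "norm_codon_lo": 20,
        "norm_codon_hi": 40,
        "span_codons": 500,
        "min_tpm": 10.0,
        "te_pseudocount": 1.0,
    },
    "proteomics": {
        "min_enrich": 3.0,
        "min_log2_lfq": 27.0,
        "min_peptides": 3,
        "invert_reverse": True,
        "rip_control_minus_bait": True,
    },
}


@dataclass
class RunConfig:
    """Typed, validated configuration for a pipeline run."""

    values: dict[str, dict[str, Any]] = field(
        default_factory=lambda: copy.deepcopy(_DEFAULTS)
    )

    def __getitem__(self, section: str) -> dict[str, Any]:
        return self.values[section]

    def get(self, section: str, key: str) -> Any:
        return self.values[section][key]

    def set(self, section: str, key: str, value: Any) -> None:
        if section not in _DEFAULTS:
            raise KeyError(f"unknown config section {section!r}")
        if key not in _DEFAULTS[section]:
            raise KeyError(f"unknown config key {section}.{key}")
        self.values[section][key] = _coerce(value, _DEFAULTS[section][key])

    @classmethod
    def load(cls, path: str) -> "RunConfig":
        parser = configparser.ConfigParser()
        with open(path) as fh:
            parser.read_file(fh)
        cfg = cls()
        for section in parser.sections():
            for key, raw in parser.items(section):
                cfg.set(section, key, raw)
        return cfg

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.dumps())

    def dumps(self) -> str:
        parser = configparser.ConfigParser()
        for section, keys in self.values.items():
            parser[section] = {k: _fmt(v) for k, v in keys.items()}
        buf = _io.StringIO()
        parser.write(buf)
        return buf.getvalue()

    def log_resolved(self) -> None:
        """Log the fully resolved configuration and seed (one line each)."""
        for section, keys in self.values.items():
            for k, v in keys.items():
                logger.info("config %s.%s = %s", section, k, _fmt(v))


def _coerce(raw: Any, default: Any) -> Any:
    if isinstance(default, bool):
        if isinstance(raw, bool):
            return raw
        if str(raw).lower() in {"true", "1", "yes"}:
            return True
        if str(raw).lower() in {"false", "0", "no"}:
            return False
        raise ValueError(f"cannot parse boolean from {raw!r}")
    if isinstance(default, int):
        return int(raw)
    if isinstance(default, float):
        return float(raw)
    return str(raw)


def _fmt(value: Any) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


def parse_motifs(spec: str, alphabet: str = "T") -> list[str]:
    """Parse a comma-separated motif list, normalizing the alphabet."""
    from .models import normalize_alphabet

    return [normalize_alphabet(m.strip(), alphabet) for m in spec.split(",") if m.strip()]
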