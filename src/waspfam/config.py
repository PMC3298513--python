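"""Flat sectioned key/value run configuration.

Every tunable of the pipeline has a compiled-in default; a config file may
override any subset.  Unknown sections or keys are errors (they are almost
always typos), and the effective configuration is echoed into the run log
by the CLI so every run is reproducible from its log alone.
"""

from __future__ import annotations

import configparser
import io

DEFAULTS: dict[str, dict] = {
    "run": {
        "seed": 1,
    },
    "detectors": {
        "wh2_gap_min": 6,
        "wh2_gap_max": 14,
        "c_flank_gap_max": 6,
        "crib_gap_min": 2,
        "crib_gap_max": 4,
        "basic_window": 8,
        "basic_fraction": 0.6,
        "ppr_window": 10,
        "ppr_fraction": 0.5,
        "ser_window": 10,
        "ser_fraction": 0.5,
        "acidic_tail": 60,
        "acidic_window": 8,
        "acidic_fraction": 0.75,
        "acidic_end_offset": 15,
        "acidic_internal_fraction": 0.875,
        "charged_window": 200,
        "charged_fraction": 0.8,
        "cc_window": 28,
        "cc_fraction": 0.6,
        "merge_gap": 10,
    },
    "profiles": {
        "pseudocount": 1.0,
        "min_column_occupancy": 0.5,
        "score_threshold_fraction": 0.6,
        "wmd_gap_min": 0,
        "wmd_gap_max": 200,
    },
    "classifier": {
        "vca_max_gap": 100,
        "terminal_a_offset": 15,
        "chg_min_length": 400,
        "cxxc_scan_len": 40,
        "triple_max_gap": 100,
        "partial_max_missing": 0.05,
        "complete_tolerance": 0.01,
        "pseudogene_min_disablements": 2,
    },
    "generator": {
        "library_seed": 20120208,
        "library_n_seqs": 12,
        "library_divergence": 0.05,
        "n_species": 20,
        "n_proteins": 200,
        "linker_min": 10,
        "linker_max": 60,
        "flank_guard": 20,
        "motif_mutation_rate": 0.0,
        "partial_prob": 0.0,
        "fragment_prob": 0.0,
        "pseudogene_prob": 0.0,
        "chg_length": 810,
    },
}


class RunConfig:
    """Typed view over DEFAULTS with optional file overrides."""

    def __init__(self, overrides: dict[str, dict] | None = None):
        self._values = {sec: dict(vals) for sec, vals in DEFAULTS.items()}
        for sec, vals in (overrides or {}).items():
            for key, val in vals.items():
                self._set(sec, key, val)

    def _set(self, section: str, key: str, value) -> None:
        if section not in self._values:
            raise KeyError(f"unknown config section [{section}]")
        if key not in self._values[section]:
            raise KeyError(f"unknown config key [{section}] {key}")
        default = DEFAULTS[section][key]
        caster = type(default)
        if isinstance(default, bool):
            value = str(value).strip().lower() in ("1", "true", "yes", "on")
        else:
            value = caster(value)
        self._values[section][key] = value

    def get(self, section: str, key: str):
        return self._values[section][key]

    def section(self, section: str) -> dict:
        return dict(self._values[section])

    @classmethod
    def load(cls, path: str) -> "RunConfig":
        parser = configparser.ConfigParser()
        with open(path) as fh:
            parser.read_file(fh)
        cfg = cls()
        for section in parser.sections():
            for key, value in parser.items(section):
                cfg._set(section, key, value)
        return cfg

    def dump(self) -> str:
        out = io.StringIO()
        for section in sorted(self._values):
            out.write(f"[{section}]\n")
            for key in sorted(self._values[section]):
                out.write(f"{key} = {self._values[section][key]}\n")
            out.write("\n")
        return out.getvalue()
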