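"""Analysis configuration: every decision threshold of the pipeline.

Defaults encode the field's standard decision rules: the 5-read
expression filter, the |log2(R/C)| > 1 homoeolog-bias threshold, the
log10(2) copy-ratio threshold, the 0.6/0.3 and 0.6/0.2 differentially
methylated gene (DMG) bounds, the 0.4/4-fold methylation-regulated gene
(MRG) rule, and the 5mC depth/FDR gates.  Config files are flat YAML
key/value documents; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised for malformed or out-of-range configuration input."""


@dataclass
class AnalysisConfig:
    min_reads: int = 5              # per-replicate raw-count eligibility floor
    heb_threshold: float = 1.0      # |log2(R/C)| above which bias is called
    copy_log10_threshold: float = math.log10(2.0)  # 0.30103, copy-gain call
    min_run: int = 3                # contiguous genes per HR segment
    alpha_count_test: float = 0.01
    alpha_ratio_test: float = 0.01
    fc_threshold: float = 4.0       # fold-change gate (see fc_gate)
    fc_gate: bool = False           # apply the fold-change gate to significance
    dm_dmg_hyper: float = 0.6       # parental |DM| above -> hyper-DMG arm
    dm_dmg_hybrid_hyper: float = 0.3
    dm_dmg_hybrid_hypo: float = 0.2
    dm_subpattern: float = 0.3      # DM threshold in the 13-pattern "strong" flag
    mrg_dm: float = 0.4
    mrg_fc: float = 4.0
    p0_error: float = 0.01          # null (bisulfite non-conversion) rate
    fdr_5mc: float = 0.05
    min_depth_5mc: int = 5          # depth > 4X means n_total >= 5
    te_proximity: int = 1000        # bp; SV within this of a TE is TE-proximal
    n_windows: int = 20             # windows per gene region profile
    dmr_alpha: float = 1e-5
    hr_pseudocount: bool = False    # add 0.5 reads before the copy ratio
    moderated: bool = True          # variance shrinkage in batch classification
    bh_correction: bool = False     # BH across pairs for the three tests
    seed: int = 0

    _PROBABILITIES = (
        "alpha_count_test",
        "alpha_ratio_test",
        "p0_error",
        "fdr_5mc",
        "dmr_alpha",
    )
    _POSITIVE = (
        "heb_threshold",
        "copy_log10_threshold",
        "fc_threshold",
        "dm_dmg_hyper",
        "dm_dmg_hybrid_hyper",
        "dm_dmg_hybrid_hypo",
        "dm_subpattern",
        "mrg_dm",
        "mrg_fc",
        "te_proximity",
        "n_windows",
    )

    def __post_init__(self) -> None:
        for key in self._PROBABILITIES:
            v = getattr(self, key)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{key} must lie in (0, 1); got {v}")
        for key in self._POSITIVE:
            if getattr(self, key) <= 0:
                raise ConfigError(f"{key} must be > 0; got {getattr(self, key)}")
        if self.min_run < 1:
            raise ConfigError(f"min_run must be >= 1; got {self.min_run}")
        if self.min_reads < 0:
            raise ConfigError(f"min_reads must be >= 0; got {self.min_reads}")
        if self.min_depth_5mc < 1:
            raise ConfigError(f"min_depth_5mc must be >= 1; got {self.min_depth_5mc}")


_FIELDS = {f.name: f for f in dataclasses.fields(AnalysisConfig)}


def load_config(path: str | Path) -> AnalysisConfig:
    """Read a flat YAML config; unspecified keys keep their defaults."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # report the offending line
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"malformed config {path}{where}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a flat key/value document")
    unknown = sorted(set(data) - set(_FIELDS))
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")
    coerced = {}
    for key, value in data.items():
        ftype = _FIELDS[key].type
        try:
            if ftype == "int":
                coerced[key] = int(value)
            elif ftype == "float":
                coerced[key] = float(value)
            elif ftype == "bool":
                coerced[key] = bool(value)
            else:
                coerced[key] = value
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"config key {key}: cannot parse {value!r}") from exc
    return AnalysisConfig(**coerced)
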