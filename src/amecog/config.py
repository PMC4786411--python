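"""Analysis configuration: one YAML document, stage-keyed.

All randomness in a pipeline run derives from the single ``seed`` via
per-stage substreams, so identical config + seed reproduces every output
bit for bit.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .errors import ValidationError


def _default_synth() -> dict:
    return {
        "raw": {
            "n_channels": 32,
            "duration_s": 48.0,
            "fs": 1200.0,
            "line_amp": 5.0,
            "bank_noise_sd": 1.0,
            "burst_snr": 5.0,
            "noise_sd": 10.0,
            "bank_size": 16,
            "n_listen_events": 16,
            "n_speak_events": 16,
            "bad_channel": 5,
        },
        "evoked": {
            "n_trials": 12,
            "noise_sd": 0.5,
            "listen_regions": {"STG": 12, "vSMC_inf": 9, "vSMC_sup": 9},
            "speak_regions": {"vSMC_inf": 9, "vSMC_sup": 9},
            "latency_map": {"STG": 0.10, "vSMC_inf": 0.20, "vSMC_sup": 0.20},
        },
        "positions": {"n": 40, "centers": [[-10.0, 0.0], [10.0, 0.0]],
                      "spread_mm": 3.0},
        "phonemes": {"n_trials": 40, "deviant_mean": 4.0},
        "strf": {"n_delays": 20, "n_freqs": 16, "n_samples": 6000,
                 "noise_sd": 0.5},
    }


def _default_stages() -> list:
    return ["preprocess", "select", "spatial", "dynamics", "geometry", "psi", "strf"]


@dataclass
class AnalysisConfig:
    """Every tunable of the pipeline, with working desk-scale defaults."""

    seed: int = 0
    out_dir: str | None = None
    stages: list = field(default_factory=_default_stages)
    synth: dict = field(default_factory=_default_synth)
    preprocess: dict = field(default_factory=lambda: {
        "notch_freqs": [60.0, 120.0, 180.0],
        "bad_threshold_sd": 2.0,
        "band": [70.0, 150.0],
        "n_filters": 8,
        "fs_out": 100.0,
    })
    selection: dict = field(default_factory=lambda: {
        "alpha": 0.01,
        "stim_window": [0.0, 0.5],
        "base_window": [-0.5, 0.0],
        "n_boot": 1000,
    })
    spatial: dict = field(default_factory=lambda: {
        "alpha": 0.05, "n_boot": 500, "k_min": 2, "k_max": 6})
    dynamics: dict = field(default_factory=lambda: {
        "max_lag": 0.75, "onset_alpha": 0.001, "coactive_band": 0.25,
        "max_pairs": 36})
    geometry: dict = field(default_factory=lambda: {
        "window": [0.0, 0.5], "k": 3, "n_boot": 50, "n_perm": 200, "q": 0.05,
        "trajectory": False, "window_len": 0.1, "step": 0.02})
    psi: dict = field(default_factory=lambda: {
        "alpha": 0.01, "correction": "bonferroni"})
    strf: dict = field(default_factory=lambda: {
        "n_folds": 10, "criterion": "correlation", "n_perm": 100,
        "sparseness_grid": [0.0, 0.5]})

    def validate(self) -> "AnalysisConfig":
        for name, a in (
            ("selection.alpha", self.selection["alpha"]),
            ("spatial.alpha", self.spatial["alpha"]),
            ("dynamics.onset_alpha", self.dynamics["onset_alpha"]),
            ("geometry.q", self.geometry["q"]),
            ("psi.alpha", self.psi["alpha"]),
        ):
            if not 0 < a < 1:
                raise ValidationError(f"{name} must be in (0, 1), got {a}")
        for name, c in (
            ("selection.n_boot", self.selection["n_boot"]),
            ("spatial.n_boot", self.spatial["n_boot"]),
            ("geometry.n_perm", self.geometry["n_perm"]),
            ("strf.n_perm", self.strf["n_perm"]),
            ("synth.evoked.n_trials", self.synth["evoked"]["n_trials"]),
        ):
            if int(c) < 1:
                raise ValidationError(f"{name} must be >= 1, got {c}")
        unknown = set(self.stages) - set(_default_stages())
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")
        return self

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as f:
            data = yaml.safe_load(f)
        cfg = cls(**data)
        return cfg.validate()
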