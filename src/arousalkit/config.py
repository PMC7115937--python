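"""Run configuration: every threshold and switch of the detection pipeline.

Defaults are the published constants of the original algorithm (SD bounds
1 and 6e3 µV, deviation ratio 5, EMG flat median 0.1 µV, noisy ratio 2 with
a >15-of-30 epoch quota, 240 s EMG baseline, 2x adaptive factors, 85%
sigma quantile, 3 s minimum event duration, 0.5 s epoch-conversion rule,
1 s event-overlap rule). A run with the default config is the
paper-faithful run; every deviation must be explicit in YAML.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class FilterConfig(_Strict):
    """Order-3 Butterworth band edges per modality, in Hz."""

    order: int = 3
    eeg_band: tuple[float, float] = (0.5, 30.0)
    eog_band: tuple[float, float] = (0.1, 5.0)
    emg_band: tuple[float, float] = (10.0, 100.0)
    zero_phase: bool = True

    @model_validator(mode="after")
    def _check_edges(self):
        for lo, hi in (self.eeg_band, self.eog_band, self.emg_band):
            if not 0 < lo < hi:
                raise ValueError(f"invalid band edges ({lo}, {hi})")
        return self


class ChannelQualityConfig(_Strict):
    sd_low_uv: float = 1.0          # whole-night SD below this => flat EEG
    sd_high_uv: float = 6.0e3       # whole-night SD above this => noisy EEG
    window_sd_ratio: float = 5.0    # per-window deviation ratio
    two_sided_ratio: bool = True    # also flag ratio < 1/ratio
    emg_flat_median_uv: float = 0.1
    emg_noisy_ratio: float = 2.0
    emg_noisy_epoch_quota: int = 15  # window noisy iff > this many 1 s epochs


class FeatureConfig(_Strict):
    theta_band: tuple[float, float] = (3.0, 7.0)
    alpha_band: tuple[float, float] = (7.0, 13.0)
    sigma_band: tuple[float, float] = (11.0, 16.0)
    beta_band: tuple[float, float] = (16.0, 30.0)
    estimator: Literal["periodogram"] = "periodogram"
    aggregation: Literal["median", "any"] = "median"
    emg_baseline_s: int = 240
    emg_local_factor: float = 2.0   # step 2: m > factor * 3-epoch median
    emg_valid_factor: float = 2.0   # step 3: m > factor * neighbourhood median
    adaptive_factor: float = 2.0    # EEG shift: power > factor * local median
    sigma_quantile: float = 0.85
    neighbourhood_epochs: int = 10  # clean epochs taken each side


class DetectorConfig(_Strict):
    min_duration_s: int = 3
    emg_margin_s: int = 1           # EMG shift within +-margin counts as concomitant
    strict_emg_overlap: bool = False
    band_handover: bool = True      # a run may mix trigger bands
    merge_gap_s: int = 0            # post-hoc merge of events closer than this


class AgreementConfig(_Strict):
    conversion_threshold_s: float = 0.5   # strict > per 1 s epoch
    event_overlap_s: float = 1.0
    kappa_variant: Literal["standard", "paper-literal"] = "standard"
    conservative_fusion: Literal["union", "intersection"] = "union"
    matching: Literal["one-to-one", "many-to-one"] = "one-to-one"


class TFConfig(_Strict):
    n_cycles: float = 7.0
    baseline: Literal["event-initial", "pre-event"] = "event-initial"
    baseline_s: float = 0.5
    fmin: float = 0.5
    fmax: float = 29.5


class RunConfig(_Strict):
    """Aggregate configuration; serialisable to/from YAML, unknown keys rejected."""

    filters: FilterConfig = FilterConfig()
    quality: ChannelQualityConfig = ChannelQualityConfig()
    features: FeatureConfig = FeatureConfig()
    detector: DetectorConfig = DetectorConfig()
    agreement: AgreementConfig = AgreementConfig()
    tf: TFConfig = TFConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)
        )
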