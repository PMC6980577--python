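"""Pipeline configuration: a flat TOML file covering every knob.

The config captures the de-correlation parameters, raster geometry,
wavelet choice, SVM hyperparameters, CV setup and the rhythm-tag
mapping.  A stable fingerprint (hash of canonicalized content of the
feature-affecting fields) travels with trained models so a model is
never applied to features computed under a different pipeline.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field

from .features import FeatureConfig
from .rr_io import DEFAULT_LABEL_MAP, RhythmLabel

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class PipelineConfig:
    alpha: float = 0.5
    beta: float = 0.75
    resolution: int = 64
    extent_ms: float = 600.0
    wavelet: str = "cdf97"
    levels: int = 3
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"
    cv_folds: int = 5
    seed: int = 0
    af_tags: tuple[str, ...] = ("AFIB",)

    features: FeatureConfig = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", FeatureConfig(
            alpha=self.alpha, beta=self.beta, resolution=self.resolution,
            extent_ms=self.extent_ms, wavelet=self.wavelet,
            levels=self.levels,
        ))
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    @property
    def label_map(self) -> dict[str, RhythmLabel]:
        return {tag: RhythmLabel.AF for tag in self.af_tags}

    def fingerprint(self) -> str:
        """Identifies the feature pipeline (model compatibility key)."""
        return self.features.fingerprint()

    def to_toml(self) -> str:
        gamma = (f'"{self.svm_gamma}"' if isinstance(self.svm_gamma, str)
                 else repr(float(self.svm_gamma)))
        tags = ", ".join(f'"{t}"' for t in self.af_tags)
        return (
            "# afdetect pipeline configuration\n"
            "[decorrelation]\n"
            f"alpha = {self.alpha!r}\n"
            f"beta = {self.beta!r}\n\n"
            "[raster]\n"
            f"resolution = {self.resolution}\n"
            f"extent_ms = {float(self.extent_ms)!r}\n\n"
            "[wavelet]\n"
            f'filter = "{self.wavelet}"\n'
            f"levels = {self.levels}\n\n"
            "[svm]\n"
            f"c = {float(self.svm_c)!r}\n"
            f"gamma = {gamma}\n\n"
            "[cv]\n"
            f"folds = {self.cv_folds}\n"
            f"seed = {self.seed}\n\n"
            "[labels]\n"
            f"af_tags = [{tags}]\n"
        )


def load_config(path) -> PipelineConfig:
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    dec = doc.get("decorrelation", {})
    ras = doc.get("raster", {})
    wav = doc.get("wavelet", {})
    svm = doc.get("svm", {})
    cv = doc.get("cv", {})
    lab = doc.get("labels", {})
    return PipelineConfig(
        alpha=dec.get("alpha", 0.5),
        beta=dec.get("beta", 0.75),
        resolution=ras.get("resolution", 64),
        extent_ms=ras.get("extent_ms", 600.0),
        wavelet=wav.get("filter", "cdf97"),
        levels=wav.get("levels", 3),
        svm_c=svm.get("c", 1.0),
        svm_gamma=svm.get("gamma", "scale"),
        cv_folds=cv.get("folds", 5),
        seed=cv.get("seed", 0),
        af_tags=tuple(lab.get("af_tags", ("AFIB",))),
    )


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(config.to_toml())
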