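"""Declarative configuration: stain profiles, denoise parameters, run setup.

Config files are YAML. A profiles file maps stain-class names to their
windows::

    ihc:
      hue_windows: [[0, 60], [320, 360]]
      sat_window: [60, 255]
      val_window: [0, 160]
    nucleus:
      hue_windows: [[200, 320]]
      sat_window: [20, 255]
      val_window: [10, 220]

A run config may additionally carry ``denoise`` (DenoiseParams fields),
``tile_size`` and ``pixel_size_um``. Precedence is CLI flag > config file >
defaults, and the fully resolved config is serialized into the output
directory for provenance.
"""

from __future__ import annotations

import dataclasses
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path

import yaml

from .color import ChannelProfile, default_profiles
from .nuclei import DenoiseParams
from .regions import DEFAULT_TILE_SIZE

__all__ = [
    "RunConfig",
    "load_profiles",
    "profiles_to_dict",
    "load_denoise_params",
    "atomic_write_text",
]


def profiles_to_dict(profiles: tuple[ChannelProfile, ChannelProfile]) -> dict:
    return {
        p.name: {
            "hue_windows": [list(wdw) for wdw in p.hue_windows],
            "sat_window": list(p.sat_window),
            "val_window": list(p.val_window),
        }
        for p in profiles
    }


def _profile_from_dict(name: str, d: dict) -> ChannelProfile:
    return ChannelProfile(
        name=name,
        hue_windows=tuple(tuple(wdw) for wdw in d["hue_windows"]),
        sat_window=tuple(d["sat_window"]),
        val_window=tuple(d["val_window"]),
    )


def load_profiles(path: str | Path | None = None,
                  overrides: dict | None = None,
                  ) -> tuple[ChannelProfile, ChannelProfile]:
    """(ihc, nucleus) profiles from a YAML file, defaults for absent classes."""
    ihc, nucleus = default_profiles()
    data: dict = {}
    if path is not None:
        data.update(yaml.safe_load(Path(path).read_text()) or {})
    if overrides:
        data.update(overrides)
    if "ihc" in data:
        ihc = _profile_from_dict("ihc", data["ihc"])
    if "nucleus" in data:
        nucleus = _profile_from_dict("nucleus", data["nucleus"])
    return ihc, nucleus


def load_denoise_params(path: str | Path | None = None,
                        overrides: dict | None = None) -> DenoiseParams:
    """DenoiseParams from a YAML file (top level or under ``denoise``)."""
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        data.update(raw.get("denoise", raw))
    if overrides:
        data.update(overrides)
    known = {f.name for f in dataclasses.fields(DenoiseParams)}
    return DenoiseParams(**{k: v for k, v in data.items() if k in known})


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one end-to-end run."""

    profiles: tuple[ChannelProfile, ChannelProfile]
    denoise: DenoiseParams = DenoiseParams()
    tile_size: int = DEFAULT_TILE_SIZE
    pixel_size_um: float = 0.23
    log_level: str = "INFO"

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        raw: dict = {}
        if path is not None:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        profiles = load_profiles(overrides=
                                 {k: raw[k] for k in ("ihc", "nucleus") if k in raw})
        denoise_overrides = dict(raw.get("denoise", {}))
        denoise_overrides.update(overrides.pop("denoise", {}))
        denoise = load_denoise_params(overrides=denoise_overrides)
        merged = {
            "tile_size": raw.get("tile_size", DEFAULT_TILE_SIZE),
            "pixel_size_um": raw.get("pixel_size_um", 0.23),
            "log_level": raw.get("log_level", "INFO"),
        }
        merged.update({k: v for k, v in overrides.items() if v is not None})
        return cls(profiles=profiles, denoise=denoise, **merged)

    def to_dict(self) -> dict:
        d = profiles_to_dict(self.profiles)
        d["denoise"] = dataclasses.asdict(self.denoise)
        d["tile_size"] = self.tile_size
        d["pixel_size_um"] = self.pixel_size_um
        d["log_level"] = self.log_level
        return d

    def save(self, path: str | Path) -> None:
        atomic_write_text(path, yaml.safe_dump(self.to_dict(), sort_keys=True))


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write via a temp file and rename, so failures leave no partial file."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
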