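"""Virtual-channel barcode encoding for ratiometric amplicon imaging.

A transcript identity is encoded not by a dedicated fluorophore but by a
*virtual code*: the vector of detection-probe (DFP) repeat counts carried by
the branched barcode across the detection spectral channels.  Every amplicon
repeat additionally binds one reference fluorescent probe (RFP), so the
detection/reference intensity ratio of a spot reads out the repeat level
directly, independent of amplicon length.  With ``C`` detection channels and
``R`` repeat levels per channel a single imaging round distinguishes ``R**C``
transcripts; sequential strip-and-reprobe rounds multiply the capacity.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ChannelConfig",
    "VirtualCode",
    "BranchedBarcode",
    "CodeBook",
    "CapacityError",
    "enumerate_codes",
    "theoretical_ratio",
    "capacity",
    "assign_codebook",
]

DFP_LENGTH_NT = 20

_CODEBOOK_SCHEMA_VERSION = 1


class CapacityError(ValueError):
    """Raised when more transcripts are requested than codes exist."""


@dataclass(frozen=True)
class ChannelConfig:
    """Spectral-channel layout of an encoding design.

    Parameters
    ----------
    n_detection_channels:
        Number of detection spectral channels, ``C``.
    n_levels:
        Maximum number of repeats of the same DFP-binding sequence per
        channel, ``R``.  Levels run from 1 to ``R``; a zero level is not a
        valid code entry (every decodable spot must light up in every
        detection channel).
    reference_channel:
        Label of the reference (RFP) channel used for normalization.
    brightness:
        Relative per-fluorophore brightness of each detection channel.
        Defaults to 1.0 everywhere.
    reference_brightness:
        Relative per-fluorophore brightness of the reference channel.
    normalization_level:
        Repeat level whose theoretical ratio is defined as
        ``brightness_c / reference_brightness``; defaults to ``n_levels``
        (the largest barcode of the design), matching the single-channel
        1–10 DFP ladder where barcode 1 has theoretical ratio 0.1.
    """

    n_detection_channels: int
    n_levels: int
    reference_channel: str = "Re"
    brightness: tuple[float, ...] | None = None
    reference_brightness: float = 1.0
    normalization_level: int | None = None

    def __post_init__(self) -> None:
        if self.n_detection_channels < 1:
            raise ValueError("need at least one detection channel")
        if self.n_levels < 1:
            raise ValueError("need at least one repeat level")
        if self.brightness is not None:
            if len(self.brightness) != self.n_detection_channels:
                raise ValueError("one brightness factor per detection channel")
            if any(b <= 0 for b in self.brightness):
                raise ValueError("brightness factors must be positive")
        if self.reference_brightness <= 0:
            raise ValueError("reference brightness must be positive")
        if self.normalization_level is not None and self.normalization_level < 1:
            raise ValueError("normalization level must be >= 1")

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(f"De{i + 1}" for i in range(self.n_detection_channels))

    @property
    def brightness_factors(self) -> np.ndarray:
        if self.brightness is None:
            return np.ones(self.n_detection_channels)
        return np.asarray(self.brightness, dtype=float)

    @property
    def norm_level(self) -> int:
        return self.n_levels if self.normalization_level is None else self.normalization_level


@dataclass(frozen=True)
class VirtualCode:
    """Repeat-level vector across detection channels (one imaging round)."""

    levels: tuple[int, ...]
    round_index: int = 0

    def __post_init__(self) -> None:
        if len(self.levels) == 0:
            raise ValueError("a code needs at least one channel level")
        if any(l < 1 for l in self.levels):
            raise ValueError("repeat levels start at 1; zero-level codes are excluded")
        if self.round_index < 0:
            raise ValueError("round_index must be >= 0")


@dataclass(frozen=True)
class BranchedBarcode:
    """Physical barcode realizing a virtual code: DFP repeats per channel."""

    code: VirtualCode
    dfp_length_nt: int = DFP_LENGTH_NT
    rfp_present: bool = True

    @property
    def dfp_repeats(self) -> tuple[int, ...]:
        return self.code.levels


def enumerate_codes(config: ChannelConfig, round_index: int = 0) -> list[VirtualCode]:
    """All ``R**C`` virtual codes of a design, lexicographically ordered."""
    return [
        VirtualCode(levels=levels, round_index=round_index)
        for levels in itertools.product(
            range(1, config.n_levels + 1), repeat=config.n_detection_channels
        )
    ]


def theoretical_ratio(code: VirtualCode, config: ChannelConfig) -> np.ndarray:
    """Expected detection/reference intensity ratio, one entry per channel.

    ``ratio_c = level_c * brightness_c / (norm_level * reference_brightness)``
    where ``norm_level`` is the design's normalization level (by default its
    maximum repeat level).  For the single-channel ladder with 10 levels the
    smallest barcode therefore has theoretical ratio 0.1.
    """
    if len(code.levels) != config.n_detection_channels:
        raise ValueError("code and config disagree on channel count")
    levels = np.asarray(code.levels, dtype=float)
    return levels * config.brightness_factors / (
        config.norm_level * config.reference_brightness
    )


def capacity(config: ChannelConfig, n_rounds: int = 1) -> int:
    """Number of distinguishable transcripts over ``n_rounds`` imaging rounds.

    Each round contributes ``R**C`` codes (e.g. two channels x three levels
    give 9 per round, 18 over two rounds).
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    return n_rounds * config.n_levels**config.n_detection_channels


@dataclass
class CodeBook:
    """Injective transcript → virtual-code map under a channel config."""

    config: ChannelConfig
    assignments: dict[str, VirtualCode] = field(default_factory=dict)

    def __post_init__(self) -> None:
        codes = list(self.assignments.values())
        if len(set(codes)) != len(codes):
            raise ValueError("codebook must be injective: duplicate codes found")

    def __len__(self) -> int:
        return len(self.assignments)

    @property
    def genes(self) -> list[str]:
        return list(self.assignments)

    def code_for(self, gene: str) -> VirtualCode:
        return self.assignments[gene]

    def gene_for(self, code: VirtualCode) -> str | None:
        for gene, c in self.assignments.items():
            if c == code:
                return gene
        return None

    def level_matrix(self) -> np.ndarray:
        """Genes x channels integer level matrix, in assignment order."""
        return np.array([c.levels for c in self.assignments.values()], dtype=int)

    def barcode_specs(self) -> pd.DataFrame:
        """Branched-barcode spec sheet: DFP repeats per transcript/channel."""
        rows = []
        for gene, code in self.assignments.items():
            bb = BranchedBarcode(code)
            for channel, repeats in zip(self.config.channel_names, bb.dfp_repeats):
                rows.append(
                    {
                        "transcript_id": gene,
                        "channel": channel,
                        "dfp_repeats": repeats,
                        "dfp_length_nt": bb.dfp_length_nt,
                        "rfp_present": bb.rfp_present,
                        "round_index": code.round_index,
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "schema_version": _CODEBOOK_SCHEMA_VERSION,
            "channels": {
                "n_detection_channels": self.config.n_detection_channels,
                "n_levels": self.config.n_levels,
                "reference_channel": self.config.reference_channel,
                "brightness": None
                if self.config.brightness is None
                else list(self.config.brightness),
                "reference_brightness": self.config.reference_brightness,
                "normalization_level": self.config.normalization_level,
            },
            "transcripts": {
                gene: {"levels": list(code.levels), "round_index": code.round_index}
                for gene, code in self.assignments.items()
            },
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, payload: dict) -> "CodeBook":
        if payload.get("schema_version") != _CODEBOOK_SCHEMA_VERSION:
            raise ValueError("unsupported codebook schema version")
        ch = payload["channels"]
        config = ChannelConfig(
            n_detection_channels=ch["n_detection_channels"],
            n_levels=ch["n_levels"],
            reference_channel=ch["reference_channel"],
            brightness=None if ch["brightness"] is None else tuple(ch["brightness"]),
            reference_brightness=ch["reference_brightness"],
            normalization_level=ch["normalization_level"],
        )
        assignments = {
            gene: VirtualCode(levels=tuple(rec["levels"]), round_index=rec["round_index"])
            for gene, rec in payload["transcripts"].items()
        }
        return cls(config=config, assignments=assignments)

    @classmethod
    def from_json(cls, source) -> "CodeBook":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls.from_dict(payload)


def assign_codebook(transcript_ids, config: ChannelConfig) -> CodeBook:
    """Assign codes to transcripts in input order (deterministic).

    Raises :class:`CapacityError` when the design cannot hold all
    transcripts, naming the smallest sufficient level count.
    """
    ids = list(transcript_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate transcript ids")
    cap = capacity(config, n_rounds=1)
    if len(ids) > cap:
        c = config.n_detection_channels
        needed_levels = int(np.ceil(len(ids) ** (1.0 / c)))
        raise CapacityError(
            f"{len(ids)} transcripts exceed the {cap}-code capacity of "
            f"{c} channels x {config.n_levels} levels; "
            f"increase n_levels to {needed_levels} (or add a channel/round)"
        )
    codes = enumerate_codes(config)
    return CodeBook(config=config, assignments=dict(zip(ids, codes)))
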