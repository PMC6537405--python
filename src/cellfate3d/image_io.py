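"""Dataset discovery, TIFF stack reading, and tabular output.

A dataset is a directory tree of single-plane grayscale TIFFs, one file per
z-slice per channel, as exported by multi-point acquisition software.  The
channel of each file is identified by a distinguishing token in its filename
(the "NamesAndTypes" convention); well and position are parsed from the
filename, and the z index is the last integer run in the stem.  Discovery is
a pure function of the directory listing and the naming configuration:
re-running it yields identical manifests, and files that match zero or more
than one channel token are reported in a rejects list, never silently
dropped.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigError, DatasetError

__all__ = [
    "ChannelRole", "StackKey", "ImageStack", "PlateLayout", "DatasetManifest",
    "discover_dataset", "read_stack", "write_scores_table", "DEFAULT_FILENAME_REGEX",
]


class ChannelRole(str, enum.Enum):
    """Biological role of an imaging channel.

    nuclear         Hoechst 33342; stains every nucleus (the denominator of
                    all pixel ratios -- mandatory for any scoring run).
    dead_membrane   ethidium homodimer (EtHd); membrane-compromised cells.
    dead_apoptotic  Apopxin; phosphatidylserine exposure at the membrane.
    proliferation   EdU click label; S-phase nuclei.
    lineage_gfp     constitutive H2B-eGFP; marks a cell lineage in co-culture.
    """

    NUCLEAR = "nuclear"
    DEAD_MEMBRANE = "dead_membrane"
    DEAD_APOPTOTIC = "dead_apoptotic"
    PROLIFERATION = "proliferation"
    LINEAGE_GFP = "lineage_gfp"

    def __str__(self) -> str:  # keep CSV/YAML values bare
        return self.value


@dataclass(frozen=True, order=True)
class StackKey:
    """Identity of one channel's z-stack: (well, position, channel)."""

    well: str
    position: int
    channel: ChannelRole

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"position must be >= 0, got {self.position}")


@dataclass
class ImageStack:
    """One channel's ordered z-series of 2D intensity planes."""

    key: StackKey
    planes: np.ndarray  # (z, y, x), non-negative
    z_spacing_um: float | None = None

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes)
        if self.planes.ndim != 3 or self.planes.shape[0] < 1:
            raise ValueError("planes must be a (z, y, x) array with >= 1 slice")
        if np.issubdtype(self.planes.dtype, np.floating) and not np.isfinite(self.planes).all():
            raise ValueError("planes contain non-finite values")
        if (self.planes < 0).any():
            raise ValueError("intensities must be >= 0")

    @property
    def n_slices(self) -> int:
        return self.planes.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[1:]


@dataclass
class PlateLayout:
    """Well -> treatment assignments with one designated vehicle control."""

    assignments: dict[str, str]
    control_label: str

    def __post_init__(self) -> None:
        if self.control_label not in self.assignments.values():
            raise ConfigError(
                f"control label {self.control_label!r} does not appear among "
                f"the well assignments"
            )

    def treatment(self, well: str) -> str:
        try:
            return self.assignments[well]
        except KeyError:
            raise ConfigError(f"well {well!r} has no treatment assignment") from None

    @classmethod
    def from_dict(cls, d: Mapping) -> "PlateLayout":
        try:
            return cls(assignments=dict(d["wells"]), control_label=str(d["control"]))
        except KeyError as e:
            raise ConfigError(f"layout is missing required key {e}") from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlateLayout":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# well/position grammar: "<well>_p<position>_...", e.g. w1_p0_z000_hoechst.tif
DEFAULT_FILENAME_REGEX = r"^(?P<well>[A-Za-z0-9-]+)_p(?P<position>\d+)_"
_Z_RUN = re.compile(r"(\d+)(?!.*\d)")  # last integer run in the stem
_TIFF_SUFFIXES = {".tif", ".tiff"}


@dataclass
class DatasetManifest:
    """Result of discovery: per-stack ordered file lists plus a rejects report."""

    stacks: dict[StackKey, list[Path]]
    rejects: list[tuple[Path, str]] = field(default_factory=list)

    def keys(self) -> set[StackKey]:
        return set(self.stacks)

    def positions(self) -> list[tuple[str, int]]:
        """Distinct (well, position) pairs in sorted order."""
        return sorted({(k.well, k.position) for k in self.stacks})


def _validate_tokens(naming_config: Mapping[ChannelRole | str, str]) -> dict[str, ChannelRole]:
    tokens: dict[str, ChannelRole] = {}
    for role, token in naming_config.items():
        role = ChannelRole(role)
        token = str(token).lower()
        if not token:
            raise ConfigError(f"empty channel token for role {role}")
        tokens[token] = role
    toks = list(tokens)
    for i, a in enumerate(toks):
        for b in toks[i + 1:]:
            if a in b or b in a:
                raise ConfigError(
                    f"channel tokens {a!r} and {b!r} overlap as substrings; "
                    f"matching would be ambiguous"
                )
    return tokens


def discover_dataset(
    root_dir: str | Path,
    naming_config: Mapping[ChannelRole | str, str],
    filename_regex: str = DEFAULT_FILENAME_REGEX,
) -> DatasetManifest:
    """Scan ``root_dir`` recursively and group TIFFs into per-channel stacks.

    Each TIFF filename must contain exactly one channel token
    (case-insensitive); files with zero or ambiguous matches, or whose names
    do not parse under ``filename_regex``, go to the rejects report.  Slices
    are ordered by the z index parsed as the last integer run in the stem.

    Raises
    ------
    ConfigError
        If two channel tokens overlap as substrings.
    DatasetError
        If no file at all could be assigned to a stack.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise DatasetError(f"dataset root {root} does not exist")
    tokens = _validate_tokens(naming_config)
    pattern = re.compile(filename_regex)

    found: dict[StackKey, list[tuple[int, Path]]] = {}
    rejects: list[tuple[Path, str]] = []
    for path in sorted(root.rglob("*")):
        if path.suffix.lower() not in _TIFF_SUFFIXES or not path.is_file():
            continue
        stem = path.stem.lower()
        matches = [r for t, r in tokens.items() if t in stem]
        if len(matches) == 0:
            rejects.append((path, "no channel token matches"))
            continue
        if len(matches) > 1:
            rejects.append((path, f"ambiguous: matches tokens for {sorted(str(m) for m in matches)}"))
            continue
        m = pattern.match(path.name)
        if m is None:
            rejects.append((path, f"filename does not match {filename_regex!r}"))
            continue
        z = _Z_RUN.search(path.stem)
        if z is None:
            rejects.append((path, "no z index (integer run) in filename"))
            continue
        key = StackKey(m.group("well"), int(m.group("position")), matches[0])
        found.setdefault(key, []).append((int(z.group(1)), path))

    if not found:
        raise DatasetError(
            f"no TIFF in {root} could be assigned to a channel stack "
            f"({len(rejects)} rejected)"
        )
    stacks = {k: [p for _, p in sorted(v)] for k, v in sorted(found.items())}
    return DatasetManifest(stacks=stacks, rejects=rejects)


def read_stack(
    key: StackKey,
    manifest: DatasetManifest | Sequence[Path],
    z_spacing_um: float | None = None,
) -> ImageStack:
    """Read one channel's slice files into an ``ImageStack`` (ascending z).

    Bit depth is preserved (8- or 16-bit planes stay integral).  A shape
    mismatch between slices is a hard error naming the offending file.
    """
    files = manifest.stacks[key] if isinstance(manifest, DatasetManifest) else list(manifest)
    if not files:
        raise DatasetError(f"no files for stack {key}")
    planes = []
    shape = None
    for f in files:
        plane = tifffile.imread(f)
        if plane.ndim != 2:
            raise DatasetError(f"{f}: expected a single 2D plane, got shape {plane.shape}")
        if shape is None:
            shape = plane.shape
        elif plane.shape != shape:
            raise DatasetError(
                f"{f}: slice shape {plane.shape} differs from first slice {shape}"
            )
        planes.append(plane)
    return ImageStack(key=key, planes=np.stack(planes), z_spacing_um=z_spacing_um)


def write_stack(stack: ImageStack, out_dir: str | Path, token: str) -> list[Path]:
    """Write a stack as one TIFF per slice using the default filename grammar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for z in range(stack.n_slices):
        p = out / f"{stack.key.well}_p{stack.key.position}_z{z:03d}_{token}.tif"
        tifffile.imwrite(p, stack.planes[z])
        paths.append(p)
    return paths


def write_scores_table(scores: Sequence, out: str | Path) -> Path:
    """Write per-treatment scores as canonical CSV.

    Rows are sorted by (treatment, metric) so the file is byte-identical for
    any input ordering; floats are fixed to 10 significant digits.
    """
    if not scores:
        raise ValueError("scores list is empty")
    rows = sorted(
        (s.treatment, s.metric, s.score, s.sem, s.n_images, s.n_positions)
        for s in scores
    )
    df = pd.DataFrame(
        rows, columns=["treatment", "metric", "score", "sem", "n_images", "n_positions"]
    )
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out, index=False, float_format="%.10g", lineterminator="\n")
    return out
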