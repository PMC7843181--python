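"""Block-structured tabular input.

A multiblock dataset is a single sample table whose columns are partitioned
into named *blocks*, each playing one of three roles:

* ``independent`` — predictor blocks (e.g. climate, altitude),
* ``dependent``   — response blocks (e.g. leaf chemistry),
* ``description`` — categorical sample metadata, one column of which carries
  the class label that drives the per-class ellipsoid analysis.

The partition is declarative: a YAML config maps block names to a role and an
ordered column list, and names the label column.  Block column sets must be
disjoint and every configured column must exist in the table header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

Role = Literal["independent", "dependent", "description"]
_ROLES: tuple[Role, ...] = ("independent", "dependent", "description")

#: string tokens read as missing in numeric cells
NA_VALUES = ["", "NA", "na", "NaN", "nan", "N/A"]


class ConfigError(ValueError):
    """Raised for an invalid block configuration."""


class AnalysisError(RuntimeError):
    """Raised when the data cannot support the requested analysis."""


@dataclass(frozen=True)
class BlockSpec:
    """One named variable block: a role plus an ordered, disjoint column list."""

    name: str
    role: Role
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ConfigError(
                f"block {self.name!r}: role must be one of {_ROLES}, got {self.role!r}"
            )
        if not self.columns:
            raise ConfigError(f"block {self.name!r}: column list is empty")
        if len(set(self.columns)) != len(self.columns):
            raise ConfigError(f"block {self.name!r}: duplicate column within block")


@dataclass(frozen=True)
class BlockConfig:
    """Full partition spec: the block list plus the class-label column."""

    blocks: tuple[BlockSpec, ...]
    label_column: str

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for spec in self.blocks:
            for col in spec.columns:
                if col in seen:
                    raise ConfigError(
                        f"column {col!r} assigned to both {seen[col]!r} and "
                        f"{spec.name!r}; blocks must be disjoint"
                    )
                seen[col] = spec.name
        names = [s.name for s in self.blocks]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate block name")
        desc = [s for s in self.blocks if s.role == "description"]
        if desc:
            if not any(self.label_column in s.columns for s in desc):
                raise ConfigError(
                    f"label column {self.label_column!r} is not in any "
                    "description-role block"
                )
        # label column may not live in a numeric block
        for spec in self.blocks:
            if spec.role != "description" and self.label_column in spec.columns:
                raise ConfigError(
                    f"label column {self.label_column!r} cannot belong to "
                    f"numeric block {spec.name!r}"
                )

    @property
    def analysed_columns(self) -> list[str]:
        cols = [c for s in self.blocks for c in s.columns]
        if self.label_column not in cols:
            cols.append(self.label_column)
        return cols

    def numeric_blocks(self) -> list[BlockSpec]:
        return [s for s in self.blocks if s.role != "description"]


@dataclass
class BlockCollection:
    """The in-memory partitioned dataset.

    ``samples`` holds all configured columns (numeric blocks parsed as float,
    missing cells as NaN) in file row order; ``class_labels`` is the aligned
    categorical label series.
    """

    samples: pd.DataFrame
    blocks: tuple[BlockSpec, ...]
    label_column: str

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def class_labels(self) -> pd.Series:
        return self.samples[self.label_column]

    @property
    def class_set(self) -> list[str]:
        return sorted(self.class_labels.astype(str).unique())

    @property
    def n_classes(self) -> int:
        return len(self.class_set)

    def block(self, name: str) -> BlockSpec:
        for spec in self.blocks:
            if spec.name == name:
                return spec
        raise KeyError(f"no block named {name!r}")

    def block_data(self, name: str) -> pd.DataFrame:
        return self.samples[list(self.block(name).columns)]

    def numeric_columns(self) -> list[str]:
        """Columns of all independent/dependent blocks, in block order."""
        return [c for s in self.blocks if s.role != "description" for c in s.columns]

    def blocks_by_role(self, role: Role) -> list[BlockSpec]:
        return [s for s in self.blocks if s.role == role]

    def replace_samples(self, samples: pd.DataFrame) -> "BlockCollection":
        return BlockCollection(samples=samples, blocks=self.blocks,
                               label_column=self.label_column)

    def to_csv(self, path: str | Path) -> None:
        self.samples.to_csv(path, index=False)


def load_config(path: str | Path) -> BlockConfig:
    """Parse a YAML block config.

    Expected layout::

        label: location
        blocks:
          climate:   {role: independent, columns: [t_mean, rain, ...]}
          chemicals: {role: dependent,   columns: [sugar, nicotine, ...]}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping) or "blocks" not in raw or "label" not in raw:
        raise ConfigError(f"{path}: config must contain 'label' and 'blocks' keys")
    specs = []
    for name, body in raw["blocks"].items():
        try:
            specs.append(
                BlockSpec(
                    name=str(name),
                    role=body["role"],
                    columns=tuple(str(c) for c in body["columns"]),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"block {name!r}: needs 'role' and 'columns'") from exc
    label = str(raw["label"])
    if not any(s.role == "description" for s in specs):
        # implicit description block holding just the label column
        specs.append(BlockSpec(name="description", role="description",
                               columns=(label,)))
    return BlockConfig(blocks=tuple(specs), label_column=label)


def save_config(config: BlockConfig, path: str | Path) -> None:
    body = {
        "label": config.label_column,
        "blocks": {
            s.name: {"role": s.role, "columns": list(s.columns)}
            for s in config.blocks
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(body, fh, sort_keys=False)


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_table(
    path: str | Path,
    config: BlockConfig,
    delimiter: str | None = None,
) -> BlockCollection:
    """Read a delimited table and partition its columns per ``config``.

    Rows keep file order.  Numeric-block cells that fail to parse, or that are
    empty/"NA", become NaN — they are flagged for the preprocessing stage, not
    dropped here.  Columns not mentioned in the config are ignored with a
    warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"data file not found: {path}")
    sep = _infer_delimiter(path, delimiter)
    table = pd.read_csv(path, sep=sep, na_values=NA_VALUES, keep_default_na=True)
    missing_cols = [c for c in config.analysed_columns if c not in table.columns]
    if missing_cols:
        raise ConfigError(
            f"configured column(s) absent from header: {missing_cols}"
        )
    extra = [c for c in table.columns if c not in config.analysed_columns]
    if extra:
        logger.warning("ignoring %d non-configured column(s): %s", len(extra), extra)
    frame = table[config.analysed_columns].copy()
    for spec in config.numeric_blocks():
        for col in spec.columns:
            frame[col] = pd.to_numeric(frame[col], errors="coerce")
    frame[config.label_column] = frame[config.label_column].astype(str)
    return BlockCollection(samples=frame, blocks=config.blocks,
                           label_column=config.label_column)


def from_frame(frame: pd.DataFrame, config: BlockConfig) -> BlockCollection:
    """Build a BlockCollection from an in-memory DataFrame (same checks as
    :func:`read_table`, no file I/O)."""
    missing_cols = [c for c in config.analysed_columns if c not in frame.columns]
    if missing_cols:
        raise ConfigError(f"configured column(s) absent from frame: {missing_cols}")
    out = frame[config.analysed_columns].copy()
    for spec in config.numeric_blocks():
        for col in spec.columns:
            out[col] = pd.to_numeric(out[col], errors="coerce")
    out[config.label_column] = out[config.label_column].astype(str)
    return BlockCollection(samples=out, blocks=config.blocks,
                           label_column=config.label_column)


def validate_partition(
    bc: BlockCollection, min_class_size: int = 1
) -> dict:
    """Summarise the partition: per-role column counts and per-class rows.

    Raises :class:`AnalysisError` if fewer than two classes are present (the
    per-class ellipsoid comparison is undefined for a single class) or if any
    class falls below ``min_class_size`` rows.
    """
    role_counts = {
        role: sum(len(s.columns) for s in bc.blocks_by_role(role))
        for role in ("independent", "dependent", "description")
    }
    class_counts = bc.class_labels.astype(str).value_counts().to_dict()
    if len(class_counts) < 2:
        raise AnalysisError(
            f"need >= 2 classes for ellipsoid comparison, found {len(class_counts)}"
        )
    too_small = {c: k for c, k in class_counts.items() if k < min_class_size}
    if too_small:
        raise AnalysisError(
            f"classes below minimum size {min_class_size}: {too_small}"
        )
    return {
        "n_samples": bc.n,
        "n_classes": bc.n_classes,
        "columns_per_role": role_counts,
        "blocks": {
            s.name: {"role": s.role, "n_columns": len(s.columns)} for s in bc.blocks
        },
        "class_counts": class_counts,
    }
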