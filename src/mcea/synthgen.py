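"""Synthetic multiblock generator.

Emulates the structure the ellipsoid-overlap method assumes: samples fall
into geographic-style classes; within each block a class is a Gaussian
cluster around a class mean; and the *class means* of a dependent block can
be linearly coupled to those of the independent blocks.  Coupling acts at the
between-class level only — the within-class residuals of different blocks are
independent — because that is the level at which shared location
characteristics express themselves.

Class means are built from per-block latent factors with a geometrically
decaying variance spectrum (``spectrum_decay`` per factor), mixed into the
observed variables by a random rotation.  The decay mirrors real
environmental tables, where a handful of dominant gradients (temperature,
elevation, ...) drive most between-location variation; it is also what makes
a low-dimensional score-space analysis informative — with an isotropic
spectrum every block's leading PC plane would be an unrelated random
projection of the latent space and no cross-block structure would survive
dimension reduction.  Coupling links the factor spaces: the dependent block's
factors are a mix of (randomly mapped) independent-block factors and its own
noise, with the map rescaled so the target block keeps its own between-class
spectrum.

The default shape mirrors a tobacco-agronomy table: 35 location classes and
three blocks of 14 (climate), 4 (altitude) and 5 (chemistry) variables.  The
between/within spread ratio (3.0 / 1.0) caps the per-variable regression R²
near ρ² · σ_b²λ̄/(σ_b²λ̄+σ_w²) ≈ 0.1 at the default coupling ρ = 0.35 — the
weak-correlation regime the method is designed for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io_config import BlockCollection, BlockConfig, BlockSpec, ConfigError, from_frame


def _default_blocks() -> dict[str, tuple[int, str]]:
    return {
        "climate": (14, "independent"),
        "altitude": (4, "independent"),
        "chemicals": (5, "dependent"),
    }


def _default_coupling() -> dict[tuple[str, str], float]:
    return {
        ("climate", "chemicals"): 0.35,
        ("altitude", "chemicals"): 0.35,
    }


@dataclass
class SyntheticConfig:
    """Generator settings; ``seed`` fixes the output bit-exactly."""

    n_classes: int = 35
    samples_per_class: int = 100
    #: block name -> (n variables, role)
    blocks: dict[str, tuple[int, str]] = field(default_factory=_default_blocks)
    #: (source block, target block) -> coupling strength in [0, 1]
    coupling: dict[tuple[str, str], float] = field(default_factory=_default_coupling)
    within_class_sd: float = 1.0
    between_class_sd: float = 3.0
    #: geometric decay of latent-factor sd per factor index (1.0 = isotropic)
    spectrum_decay: float = 0.5
    seed: int = 0
    label_column: str = "location"

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ConfigError("need n_classes >= 2")
        if self.samples_per_class < 1:
            raise ConfigError("need samples_per_class >= 1")
        for name, (dim, role) in self.blocks.items():
            if dim < 1:
                raise ConfigError(f"block {name!r}: dims must be >= 1")
            if role not in ("independent", "dependent"):
                raise ConfigError(f"block {name!r}: bad role {role!r}")
        incoming: dict[str, float] = {}
        for (src, tgt), rho in self.coupling.items():
            if src not in self.blocks or tgt not in self.blocks:
                raise ConfigError(f"coupling refers to unknown block: {(src, tgt)}")
            if src == tgt:
                raise ConfigError("self-coupling is not allowed")
            if not 0 <= rho <= 1:
                raise ConfigError(f"coupling {(src, tgt)} = {rho} outside [0, 1]")
            incoming[tgt] = incoming.get(tgt, 0.0) + rho**2
        for tgt, s in incoming.items():
            if s > 1 + 1e-12:
                raise ConfigError(
                    f"block {tgt!r}: sum of squared incoming couplings {s:.3f} > 1"
                )
        if self.within_class_sd <= 0 or self.between_class_sd < 0:
            raise ConfigError("within_class_sd must be > 0, between_class_sd >= 0")
        if not 0 < self.spectrum_decay <= 1:
            raise ConfigError("spectrum_decay must be in (0, 1]")

    def block_config(self) -> BlockConfig:
        specs = [
            BlockSpec(
                name=name,
                role=role,  # type: ignore[arg-type]
                columns=tuple(f"{name}_{i + 1:02d}" for i in range(dim)),
            )
            for name, (dim, role) in self.blocks.items()
        ]
        specs.append(BlockSpec(name="description", role="description",
                               columns=(self.label_column,)))
        return BlockConfig(blocks=tuple(specs), label_column=self.label_column)


@dataclass
class ArtifactRecord:
    """Ground truth for injected missingness and outliers."""

    missing_cells: list[tuple[int, str]]
    outlier_cells: list[tuple[int, str]]

    @property
    def missing_rows(self) -> list[int]:
        return sorted({r for r, _ in self.missing_cells})

    @property
    def outlier_rows(self) -> list[int]:
        return sorted({r for r, _ in self.outlier_cells})


def generate(cfg: SyntheticConfig) -> BlockCollection:
    """Draw the multiblock table.

    Per class c and block b, latent whitened factors u_b(c) ~ N(0, I) are
    shaped by the block's decaying spectrum Λ_b^1/2 = diag(decay^j).  A block
    with incoming couplings {(s → b): ρ_s} gets shaped factor coordinates

        g_b(c) = Σ_s ρ_s · M_{s→b} (Λ_s^1/2 u_s(c))
                 + sqrt(1 − Σ_s ρ_s²) · Λ_b^1/2 u_b(c),

    where each Gaussian map M is drawn once per seed and rescaled row-wise so
    the coupled part reproduces the target block's own spectrum (coordinate j
    of M Λ_s^1/2 u_s has variance decay^2j).  Class means are
    μ_b(c) = σ_between · R_b g_b(c) with R_b a random rotation mixing the
    factors into the observed variables; samples are μ_b(c) plus isotropic
    Gaussian noise of sd σ_within.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    names = list(cfg.blocks)
    dims = {b: cfg.blocks[b][0] for b in names}
    spectrum = {
        b: cfg.spectrum_decay ** np.arange(dims[b]) for b in names
    }
    # latent per-class whitened factors, fixed draw order for determinism
    latent = {b: rng.standard_normal((cfg.n_classes, dims[b])) for b in names}
    # one cross-block factor map per coupled pair; row j rescaled so the
    # mapped source factors carry the target's spectrum sd at coordinate j
    maps = {}
    for (src, tgt), _rho in sorted(cfg.coupling.items()):
        M = rng.standard_normal((dims[tgt], dims[src]))
        row_sd = np.linalg.norm(M * spectrum[src][None, :], axis=1)
        maps[(src, tgt)] = M * (spectrum[tgt] / row_sd)[:, None]
    # random rotation per block: observed variables are factor mixtures
    rotations = {}
    for b in names:
        Q, _ = np.linalg.qr(rng.standard_normal((dims[b], dims[b])))
        rotations[b] = Q
    class_means = {}
    for b in names:
        inc = sorted((s, r) for (s, t), r in cfg.coupling.items() if t == b)
        rho2 = sum(r**2 for _, r in inc)
        shaped = np.sqrt(max(0.0, 1.0 - rho2)) * latent[b] * spectrum[b][None, :]
        for src, rho in inc:
            shaped = shaped + rho * (latent[src] * spectrum[src][None, :]) @ maps[(src, b)].T
        class_means[b] = cfg.between_class_sd * shaped @ rotations[b].T

    n_total = cfg.n_classes * cfg.samples_per_class
    width = len(str(cfg.n_classes))
    labels = np.repeat(
        [f"C{i + 1:0{width}d}" for i in range(cfg.n_classes)],
        cfg.samples_per_class,
    )
    data = {}
    for b in names:
        noise = rng.standard_normal((n_total, dims[b])) * cfg.within_class_sd
        means = np.repeat(class_means[b], cfg.samples_per_class, axis=0)
        block = means + noise
        for i in range(dims[b]):
            data[f"{b}_{i + 1:02d}"] = block[:, i]
    data[cfg.label_column] = labels
    frame = pd.DataFrame(data)
    return from_frame(frame, cfg.block_config())


def inject_artifacts(
    bc: BlockCollection,
    missing_rate: float = 0.0,
    outlier_rate: float = 0.0,
    seed: int = 0,
) -> tuple[BlockCollection, ArtifactRecord]:
    """Blank random numeric cells and plant gross outliers.

    Outliers are set to Q3 + 10·IQR of their column (computed on the clean
    values), far beyond the 1.5·IQR Tukey fence, so the box-plot filter is
    guaranteed to remove them whenever the column has positive IQR.  Returns
    the modified collection and the ground-truth cell lists.
    """
    for name, rate in (("missing_rate", missing_rate),
                       ("outlier_rate", outlier_rate)):
        if not 0 <= rate < 0.5:
            raise ConfigError(f"{name} must be in [0, 0.5), got {rate}")
    rng = np.random.default_rng(seed)
    frame = bc.samples.copy()
    cols = bc.numeric_columns()
    n = len(frame)
    missing_cells: list[tuple[int, str]] = []
    outlier_cells: list[tuple[int, str]] = []
    if outlier_rate > 0:
        q1 = frame[cols].quantile(0.25)
        q3 = frame[cols].quantile(0.75)
        iqr = q3 - q1
        mask = rng.random((n, len(cols))) < outlier_rate
        for j, c in enumerate(cols):
            rows = np.nonzero(mask[:, j])[0]
            frame.iloc[rows, frame.columns.get_loc(c)] = q3[c] + 10.0 * iqr[c]
            outlier_cells.extend((int(frame.index[r]), c) for r in rows)
    if missing_rate > 0:
        mask = rng.random((n, len(cols))) < missing_rate
        for j, c in enumerate(cols):
            rows = np.nonzero(mask[:, j])[0]
            frame.iloc[rows, frame.columns.get_loc(c)] = np.nan
            missing_cells.extend((int(frame.index[r]), c) for r in rows)
    return bc.replace_samples(frame), ArtifactRecord(
        missing_cells=missing_cells, outlier_cells=outlier_cells
    )
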