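"""SPOT-array layout modelling and synthetic fluorescence generation.

The physical design mirrors a triplicate-by-three-array screen: every
library peptide is spotted in triplicate on each of three membranes (nine
spots in total) with all spot positions randomly permuted per array, and the
20 homotrimers (AAA ... YYY) ride along as internal controls.

Because no spot-level scan data is publicly available for this assay, the
screen is emulated by a latent log-affinity model.  Each peptide q carries a
latent log-affinity mu(q, c) per protein channel c (Col IV, Col I, Alb); one
feature-space cluster is "planted" as selective by elevating its Col IV
affinity and depressing its Col I / Alb affinities.  Observed spot
intensities are log-normal around baseline + affinity with a per-array
offset and independent per-spot noise:

    log I(spot) = b_c + mu(q, c) + a(array, c) + eps(spot),
    a ~ N(0, sigma_array^2),  eps ~ N(0, sigma_spot^2),  I = exp(log I).

All randomness flows from explicit integer seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aaindex import AMINO_ACIDS
from .hier_clustering import ClusterModel

#: Default protein channels; the first is the screening target.
CHANNELS = ("ColIV", "ColI", "Alb")

#: The 20 homotrimer internal controls (AAA, CCC, ..., YYY).
HOMOTRIMER_CONTROLS: tuple[str, ...] = tuple(aa * 3 for aa in AMINO_ACIDS)


@dataclass(frozen=True)
class ArrayLayout:
    """Spot positions of a multi-array design.

    ``spots`` columns: array (1-based), row, col, peptide, replicate
    (1..n_replicates), role ('library' | 'control').
    """

    spots: pd.DataFrame
    n_arrays: int
    n_replicates: int
    grid_shape: tuple[int, int]
    seed: int

    @property
    def library_peptides(self) -> list[str]:
        lib = self.spots.loc[self.spots.role == "library", "peptide"]
        return sorted(lib.unique())

    @property
    def control_peptides(self) -> list[str]:
        ctl = self.spots.loc[self.spots.role == "control", "peptide"]
        return sorted(ctl.unique())


def design_arrays(
    representatives: list[str],
    controls: list[str] | None = None,
    n_arrays: int = 3,
    n_replicates: int = 3,
    seed: int = 0,
    grid_shape: tuple[int, int] | None = None,
) -> ArrayLayout:
    """Lay out library peptides + controls in replicate with random positions.

    Every peptide (library and control alike) appears ``n_replicates`` times
    per array; positions are an independent seeded permutation per array to
    avoid positional bias.  ``grid_shape`` defaults to the tightest
    near-square grid that holds all spots.
    """
    if not representatives:
        raise ValueError("representative list is empty")
    controls = list(HOMOTRIMER_CONTROLS) if controls is None else list(controls)
    entries = [(p, "library") for p in representatives] + [
        (p, "control") for p in controls
    ]
    per_array = len(entries) * n_replicates
    if grid_shape is None:
        ncol = math.ceil(math.sqrt(per_array))
        nrow = math.ceil(per_array / ncol)
        grid_shape = (nrow, ncol)
    nrow, ncol = grid_shape
    if nrow * ncol < per_array:
        raise ValueError(
            f"grid {grid_shape} holds {nrow * ncol} spots but design needs {per_array}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    cells = [(r, c) for r in range(1, nrow + 1) for c in range(1, ncol + 1)]
    for a in range(1, n_arrays + 1):
        stock = [
            (pep, role, rep)
            for (pep, role) in entries
            for rep in range(1, n_replicates + 1)
        ]
        placement = rng.permutation(len(cells))[: len(stock)]
        for (pep, role, rep), cell_idx in zip(stock, placement):
            r, c = cells[cell_idx]
            rows.append((a, r, c, pep, rep, role))
    spots = pd.DataFrame(
        rows, columns=["array", "row", "col", "peptide", "replicate", "role"]
    )
    return ArrayLayout(
        spots=spots,
        n_arrays=n_arrays,
        n_replicates=n_replicates,
        grid_shape=grid_shape,
        seed=seed,
    )


@dataclass(frozen=True)
class AffinityTruth:
    """Latent per-peptide, per-channel log-affinities with a planted cluster.

    Non-planted peptides get channel-exchangeable affinities
    mu(q, c) = base(q) + eta(q, c) with eta iid across channels.  Members of
    the planted cluster get mu = base + delta_target on the target channel
    and exactly base - delta_offtarget on every other channel.
    """

    mu: pd.DataFrame  # index peptide, columns channels
    planted_cluster: int | None
    planted_peptides: frozenset[str]
    delta_target: float
    delta_offtarget: float
    channels: tuple[str, ...] = CHANNELS
    target_channel: str = CHANNELS[0]

    def is_planted(self, peptide: str) -> bool:
        return peptide in self.planted_peptides


def make_affinity_truth(
    peptides: list[str],
    planted_peptides: set[str] | frozenset[str] = frozenset(),
    planted_cluster: int | None = None,
    delta_target: float = 1.0,
    delta_offtarget: float = 1.0,
    sigma_base: float = 0.5,
    sigma_channel: float = 0.1,
    seed: int = 0,
    channels: tuple[str, ...] = CHANNELS,
    target_channel: str = CHANNELS[0],
) -> AffinityTruth:
    """Draw latent affinities for ``peptides`` with one planted selective set."""
    if target_channel not in channels:
        raise ValueError(f"target channel {target_channel!r} not in {channels}")
    unknown = set(planted_peptides) - set(peptides)
    if unknown:
        raise ValueError(f"planted peptides not in library: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    base = rng.normal(0.0, sigma_base, size=len(peptides))
    eta = rng.normal(0.0, sigma_channel, size=(len(peptides), len(channels)))
    mu = base[:, None] + eta
    planted_rows = np.array([p in planted_peptides for p in peptides])
    for j, c in enumerate(channels):
        shift = delta_target if c == target_channel else -delta_offtarget
        mu[planted_rows, j] = base[planted_rows] + shift
    return AffinityTruth(
        mu=pd.DataFrame(mu, index=list(peptides), columns=list(channels)),
        planted_cluster=planted_cluster,
        planted_peptides=frozenset(planted_peptides),
        delta_target=delta_target,
        delta_offtarget=delta_offtarget,
        channels=channels,
        target_channel=target_channel,
    )


def planted_truth_from_model(
    model: ClusterModel,
    layout_peptides: list[str],
    planted_cluster: int,
    **kwargs,
) -> AffinityTruth:
    """Affinity truth whose planted set is a whole feature-space cluster.

    Planting at cluster level (rather than per peptide) makes downstream
    recovery a joint test of the clustering and the selectivity analysis.
    """
    members = set(model.members(planted_cluster))
    planted = members & set(layout_peptides)
    return make_affinity_truth(
        layout_peptides,
        planted_peptides=planted,
        planted_cluster=planted_cluster,
        **kwargs,
    )


@dataclass(frozen=True)
class NoiseConfig:
    """Noise model of the synthetic scanner, in log-intensity units."""

    sigma_array: float = 0.1
    sigma_spot: float = 0.2
    baselines: dict[str, float] = field(
        default_factory=lambda: {c: 6.0 for c in CHANNELS}
    )

    def __post_init__(self) -> None:
        if self.sigma_array < 0 or self.sigma_spot < 0:
            raise ValueError("noise SDs must be non-negative")


def simulate_intensities(
    layout: ArrayLayout,
    truth: AffinityTruth,
    noise: NoiseConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a spot-level fluorescence table for every channel.

    Returns columns: array, row, col, peptide, replicate, role, channel,
    intensity (positive, arbitrary fluorescence units).
    """
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(seed)
    channels = truth.channels
    missing = set(layout.spots.peptide) - set(truth.mu.index)
    if missing:
        raise ValueError(f"no latent affinity for peptides: {sorted(missing)[:5]}...")
    offsets = {
        (a, c): rng.normal(0.0, noise.sigma_array)
        for a in range(1, layout.n_arrays + 1)
        for c in channels
    }
    frames = []
    spots = layout.spots
    mu_lut = truth.mu
    for c in channels:
        log_i = (
            noise.baselines[c]
            + mu_lut.loc[spots.peptide, c].to_numpy()
            + np.array([offsets[(a, c)] for a in spots.array])
            + rng.normal(0.0, noise.sigma_spot, size=len(spots))
        )
        df = spots.copy()
        df["channel"] = c
        df["intensity"] = np.exp(log_i)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[
        ["array", "row", "col", "peptide", "replicate", "role", "channel", "intensity"]
    ]
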