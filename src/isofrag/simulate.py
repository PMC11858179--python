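"""Synthetic energy-resolved MS/MS series with known ground truth.

The generator emulates the statistical structure that the analysis stages
assume for the three isomeric carnosine-TAT1 peptides: a logistic
precursor-depletion curve SY(V) = 1/(1+exp((V-V50)/w)); dominant,
isomer-shared neutral-loss channels in m/z 800-900; low-intensity
isomer-specific channels in m/z 600-800; and consecutive-fragmentation
chains in which each child channel drains its parent through a later
logistic gate — guaranteeing the child's curve peaks lower and later than
its parent's.  Kinetics are phenomenological logistics, not RRKM theory:
sufficient to reproduce the qualitative curve shapes the method reads.

Every channel may carry the :class:`~isofrag.masses.IonSpec` that defines
its m/z, so downstream recovery (PCA ranking, annotation) can be scored
against planted truth.  Identical seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .fragments import CatalogueConfig, FragmentCatalogue, build_catalogue
from .masses import (
    CAR_TAT1,
    T_CAR_T,
    TAT1_CAR,
    IonKind,
    IonSpec,
    default_losses,
)
from .spectra import Spectrum, SpectrumMeta, SpectrumSeries, write_mgf

__all__ = [
    "NoiseConfig",
    "Channel",
    "AnalyteConfig",
    "SimConfig",
    "SimTruth",
    "simulate",
    "default_paper_scenario",
    "spectrum_from_ions",
    "write_simulation",
]

#: arbitrary-units scale of the synthetic total ion current
TIC_SCALE = 1.0e5


def _logistic(x: float) -> float:
    # guard against overflow for extreme arguments
    if x > 700:
        return 1.0
    if x < -700:
        return 0.0
    return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class NoiseConfig:
    """Multiplicative log-normal intensity noise, additive uniform baseline
    (as a fraction of the base peak), and Gaussian m/z jitter (Th)."""

    mult_sigma: float = 0.05
    baseline: float = 0.001
    mz_jitter: float = 0.003

    @property
    def is_zero(self) -> bool:
        return self.mult_sigma == 0 and self.baseline == 0 and self.mz_jitter == 0


@dataclass(frozen=True)
class Channel:
    """One fragmentation channel.

    A *primary* channel (``parent is None``) receives a share of the
    depleted precursor intensity proportional to weight x logistic gate.
    A *consecutive* channel drains ``weight`` x gate of its parent's
    current intensity, so its breakdown curve is right-shifted and lower.
    """

    id: str
    mz: float
    weight: float
    onset_v: float
    steepness: float = 2.5
    parent: str | None = None
    group_specific: bool = False
    ion: IonSpec | None = None

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(f"channel {self.id!r}: weight must be >= 0")
        if self.steepness <= 0:
            raise ValueError(f"channel {self.id!r}: steepness must be > 0")

    def gate(self, voltage: float) -> float:
        return _logistic((voltage - self.onset_v) / self.steepness)


@dataclass(frozen=True)
class AnalyteConfig:
    peptide_id: str
    precursor_mz: float
    channels: tuple[Channel, ...]
    precursor_charge: int = 2
    precursor_v50: float = 32.0
    precursor_width: float = 2.9

    def __post_init__(self) -> None:
        ids = [c.id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.peptide_id}: duplicate channel ids")
        self.topological_order()  # validates parents and acyclicity

    def topological_order(self) -> list[Channel]:
        by_id = {c.id: c for c in self.channels}
        order: list[Channel] = []
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(c: Channel) -> None:
            st = state.get(c.id)
            if st == 1:
                return
            if st == 0:
                raise ValueError(
                    f"{self.peptide_id}: cycle in channel graph at {c.id!r}"
                )
            state[c.id] = 0
            if c.parent is not None:
                if c.parent not in by_id:
                    raise ValueError(
                        f"{self.peptide_id}: channel {c.id!r} references "
                        f"unknown parent {c.parent!r}"
                    )
                visit(by_id[c.parent])
            state[c.id] = 1
            order.append(c)

        for c in self.channels:
            visit(c)
        return order


@dataclass(frozen=True)
class SimConfig:
    analytes: tuple[AnalyteConfig, ...]
    voltages: tuple[float, ...] = tuple(float(v) for v in range(20, 43, 2))
    replicates: int = 3
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 20

    def __post_init__(self) -> None:
        if not self.analytes:
            raise ValueError("need at least one analyte")
        if any(b <= a for a, b in zip(self.voltages, self.voltages[1:])):
            raise ValueError("voltage grid must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


#: cap on the total share children may drain from a parent at any voltage
_MAX_CHILD_DRAIN = 0.95


def _channel_fractions(analyte: AnalyteConfig, voltage: float) -> tuple[float, dict[str, float]]:
    """Noiseless (SY, per-channel TIC fraction) at one voltage.
    SY + sum of fractions is 1 by construction."""
    sy = _logistic(-(voltage - analyte.precursor_v50) / analyte.precursor_width)
    depleted = 1.0 - sy
    primaries = [c for c in analyte.channels if c.parent is None]
    raw = {c.id: c.weight * c.gate(voltage) for c in primaries}
    total_raw = sum(raw.values())
    amounts: dict[str, float] = {c.id: 0.0 for c in analyte.channels}
    if total_raw <= 0.0:
        # no channel is open: the precursor keeps everything
        return sy + depleted, amounts
    for cid, r in raw.items():
        amounts[cid] = depleted * r / total_raw

    children_of: dict[str, list[Channel]] = {}
    for c in analyte.topological_order():
        if c.parent is not None:
            children_of.setdefault(c.parent, []).append(c)
    for parent in analyte.topological_order():
        kids = children_of.get(parent.id)
        if not kids:
            continue
        shares = [k.weight * k.gate(voltage) for k in kids]
        total_share = sum(shares)
        if total_share > _MAX_CHILD_DRAIN:
            shares = [s * _MAX_CHILD_DRAIN / total_share for s in shares]
        parent_amount = amounts[parent.id]
        for k, s in zip(kids, shares):
            amounts[k.id] += parent_amount * s
        amounts[parent.id] = parent_amount * (1.0 - sum(shares))
    return sy, amounts


@dataclass
class SimTruth:
    """Noiseless ground truth of a simulation run.

    ``fractions[peptide_id]`` is a voltage-indexed DataFrame with an ``SY``
    column plus one column per channel id; at every voltage the row sums
    to 1.  ``channel_mz`` and ``group_specific`` identify the planted
    channels; ``channel_ion`` carries their generating ion specs.
    """

    fractions: dict[str, pd.DataFrame]
    channel_mz: dict[str, dict[str, float]]
    group_specific: dict[str, list[str]]
    channel_ion: dict[str, dict[str, IonSpec | None]]

    def diagnostics_at(self, peptide_id: str, voltage: float) -> pd.DataFrame:
        """Planted group-specific channels with their true TIC fractions at
        the voltage nearest to ``voltage``."""
        df = self.fractions[peptide_id]
        v = df.index[int(np.argmin(np.abs(df.index.to_numpy() - voltage)))]
        rows = []
        for cid in self.group_specific[peptide_id]:
            rows.append(
                {
                    "channel_id": cid,
                    "mz": self.channel_mz[peptide_id][cid],
                    "abundance": float(df.loc[v, cid]),
                }
            )
        return pd.DataFrame(rows)


def simulate(config: SimConfig) -> tuple[list[SpectrumSeries], SimTruth]:
    """Generate one SpectrumSeries per analyte plus the noiseless truth."""
    rng = np.random.default_rng(config.seed)
    series: list[SpectrumSeries] = []
    fractions: dict[str, pd.DataFrame] = {}
    channel_mz: dict[str, dict[str, float]] = {}
    group_specific: dict[str, list[str]] = {}
    channel_ion: dict[str, dict[str, IonSpec | None]] = {}

    for analyte in config.analytes:
        rows = []
        for v in config.voltages:
            sy, amounts = _channel_fractions(analyte, v)
            rows.append({"SY": sy, **amounts})
        truth_df = pd.DataFrame(rows, index=pd.Index(config.voltages, name="voltage"))
        fractions[analyte.peptide_id] = truth_df
        channel_mz[analyte.peptide_id] = {c.id: c.mz for c in analyte.channels}
        group_specific[analyte.peptide_id] = [
            c.id for c in analyte.channels if c.group_specific
        ]
        channel_ion[analyte.peptide_id] = {c.id: c.ion for c in analyte.channels}

        spectra: list[Spectrum] = []
        for v in config.voltages:
            row = truth_df.loc[v]
            base_mz = np.array(
                [analyte.precursor_mz] + [c.mz for c in analyte.channels]
            )
            base_int = np.array(
                [row["SY"]] + [row[c.id] for c in analyte.channels]
            ) * TIC_SCALE
            for rep in range(1, config.replicates + 1):
                intens = base_int * rng.lognormal(
                    0.0, config.noise.mult_sigma, size=base_int.shape
                )
                if config.noise.baseline > 0:
                    intens = intens + rng.uniform(
                        0.0,
                        config.noise.baseline * base_int.max(),
                        size=base_int.shape,
                    )
                mzs = base_mz + rng.normal(
                    0.0, config.noise.mz_jitter, size=base_mz.shape
                ) if config.noise.mz_jitter > 0 else base_mz.copy()
                keep = intens > 0
                meta = SpectrumMeta(
                    peptide_id=analyte.peptide_id,
                    voltage=v,
                    replicate=rep,
                    precursor_mz=analyte.precursor_mz,
                    precursor_charge=analyte.precursor_charge,
                )
                spectra.append(Spectrum(mzs[keep], intens[keep], meta))
        series.append(SpectrumSeries(spectra))

    return series, SimTruth(fractions, channel_mz, group_specific, channel_ion)


# ---------------------------------------------------------------------------
# the default three-isomer scenario


def _catalogue_mz(cat: FragmentCatalogue, ion: IonSpec) -> tuple[IonSpec, float]:
    """Locate an ion (by dedup key) in a catalogue; returns the catalogue's
    entry and m/z so the scenario never hard-codes numbers."""
    key = ion.dedup_key()
    for cand, mz in zip(cat.ions, cat.mzs):
        if cand.dedup_key() == key:
            return cand, mz
    raise KeyError(f"ion {ion} not found in catalogue of {cat.peptide.id}")


def default_paper_scenario(
    seed: int = 20,
    replicates: int = 3,
    noise: NoiseConfig | None = None,
) -> SimConfig:
    """The study conditions: three isomeric doubly protonated peptides
    (precursor m/z ~895.04), voltages 20-42 V in 2 V steps, shared dominant
    precursor-loss channels in m/z 800-900, and low-intensity
    isomer-specific channels in m/z 600-800.

    Shared channels: [M+2H-NH3]2+, [M+2H-CH2N2]2+, [M+2H-CH5N3]2+ and the
    consecutive [M+2H-CH5N3-NH3]2+.  Specific channels: the y12 loss series
    for Car-TAT1, the scrambling-route (internal) b-type series for
    T-Car-T, and b10/b11 loss ions for TAT1-Car.  All m/z values are looked
    up in the fragment catalogues, never typed in.
    """
    noise = noise if noise is not None else NoiseConfig()
    losses = default_losses()
    nh3, h2o = losses["ammonia"], losses["water"]
    cdi, gua = losses["carbodiimide"], losses["guanidine"]

    cats = {
        seq.id: build_catalogue(
            seq, CatalogueConfig(scrambling=(seq.id == "T-Car-T"))
        )
        for seq in (CAR_TAT1, T_CAR_T, TAT1_CAR)
    }

    def ch(cat, ion, **kw) -> Channel:
        cat_ion, mz = _catalogue_mz(cat, ion)
        return Channel(mz=mz, ion=cat_ion, **kw)

    def shared_channels(cat, seq) -> list[Channel]:
        prec = lambda *ls: IonSpec(IonKind.PRECURSOR, seq.residues, 2, ls)
        return [
            ch(cat, prec(nh3), id="M-NH3", weight=1.0, onset_v=27.0),
            ch(cat, prec(cdi), id="M-CH2N2", weight=0.8, onset_v=28.0),
            ch(cat, prec(gua), id="M-CH5N3", weight=0.9, onset_v=29.0),
            ch(cat, prec(gua, nh3), id="M-CH5N3-NH3", weight=0.45,
               onset_v=33.0, parent="M-CH5N3"),
        ]

    analytes: list[AnalyteConfig] = []

    # Car-TAT1: carnosine N-terminal; diagnostics are the y12 loss series
    cat = cats["Car-TAT1"]
    y12 = CAR_TAT1.residues[2:]
    y12_ion = lambda *ls: IonSpec(IonKind.Y, y12, 2, (h2o, nh3) + ls)
    b2_ion = IonSpec(IonKind.B, CAR_TAT1.residues[:2], 1)
    car_channels = shared_channels(cat, CAR_TAT1) + [
        ch(cat, y12_ion(), id="y12-H2O-NH3", weight=0.050, onset_v=30.0,
           group_specific=True),
        ch(cat, y12_ion(nh3), id="y12-H2O-2NH3", weight=0.30, onset_v=33.0,
           parent="y12-H2O-NH3", group_specific=True),
        ch(cat, y12_ion(cdi), id="y12-H2O-NH3-CH2N2", weight=0.20, onset_v=34.0,
           parent="y12-H2O-NH3", group_specific=True),
        ch(cat, y12_ion(gua), id="y12-H2O-NH3-CH5N3", weight=0.12, onset_v=35.0,
           parent="y12-H2O-NH3", group_specific=True),
        ch(cat, b2_ion, id="b2", weight=0.010, onset_v=31.0),
    ]
    analytes.append(
        AnalyteConfig("Car-TAT1", _catalogue_mz(
            cat, IonSpec(IonKind.PRECURSOR, CAR_TAT1.residues, 2))[1],
            tuple(car_channels))
    )

    # T-Car-T: carnosine central; diagnostics come from the scrambling route
    # (cyclisation puts carnosine C-terminal, water loss, then reopening)
    cat = cats["T-Car-T"]
    doubled = T_CAR_T.residues * 2
    b_beta = doubled[9 : 9 + 12]  # RRRPSGRKKRRQ: all residues except bA-H
    bb_ion = lambda *ls: IonSpec(IonKind.INTERNAL_B, b_beta, 2, (h2o,) + ls)
    t_channels = shared_channels(cat, T_CAR_T) + [
        ch(cat, bb_ion(), id="bbeta-H2O", weight=0.062, onset_v=30.0,
           group_specific=True),
        ch(cat, bb_ion(nh3), id="bbeta-H2O-NH3", weight=0.32, onset_v=33.0,
           parent="bbeta-H2O", group_specific=True),
        ch(cat, bb_ion(cdi), id="bbeta-H2O-CH2N2", weight=0.21, onset_v=34.0,
           parent="bbeta-H2O", group_specific=True),
        ch(cat, bb_ion(gua), id="bbeta-H2O-CH5N3", weight=0.13, onset_v=35.0,
           parent="bbeta-H2O", group_specific=True),
    ]
    analytes.append(
        AnalyteConfig("T-Car-T", _catalogue_mz(
            cat, IonSpec(IonKind.PRECURSOR, T_CAR_T.residues, 2))[1],
            tuple(t_channels))
    )

    # TAT1-Car: carnosine C-terminal; diagnostics are conventional b ions
    # and their losses
    cat = cats["TAT1-Car"]
    b10 = IonSpec(IonKind.B, TAT1_CAR.residues[:10], 2)
    b11 = IonSpec(IonKind.B, TAT1_CAR.residues[:11], 2)
    tat_channels = shared_channels(cat, TAT1_CAR) + [
        ch(cat, b10, id="b10", weight=0.034, onset_v=30.0, group_specific=True),
        ch(cat, b10.with_losses(cdi), id="b10-CH2N2", weight=0.30,
           onset_v=33.0, parent="b10", group_specific=True),
        ch(cat, b11, id="b11", weight=0.022, onset_v=31.0, group_specific=True),
        ch(cat, b11.with_losses(nh3), id="b11-NH3", weight=0.26,
           onset_v=34.0, parent="b11", group_specific=True),
    ]
    analytes.append(
        AnalyteConfig("TAT1-Car", _catalogue_mz(
            cat, IonSpec(IonKind.PRECURSOR, TAT1_CAR.residues, 2))[1],
            tuple(tat_channels))
    )

    return SimConfig(
        analytes=tuple(analytes),
        replicates=replicates,
        noise=noise,
        seed=seed,
    )


def spectrum_from_ions(
    ions_with_mz: Iterable[tuple[IonSpec, float]],
    meta: SpectrumMeta,
    intensities: Iterable[float] | None = None,
) -> Spectrum:
    """Noiseless spectrum with one peak per (ion, m/z) pair — ground truth
    for annotation round-trip checks."""
    pairs = list(ions_with_mz)
    mzs = np.array([mz for _, mz in pairs])
    if intensities is None:
        ints = np.full(len(pairs), 100.0)
    else:
        ints = np.asarray(list(intensities), dtype=float)
    return Spectrum(mzs, ints, meta)


def write_simulation(
    out_dir: str | Path,
    series: list[SpectrumSeries],
    truth: SimTruth,
) -> None:
    """Write one MGF per analyte plus delimited truth files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for s in series:
        safe = s.peptide_id.replace("/", "_")
        write_mgf(s.spectra, out_dir / f"{safe}.mgf")
        truth.fractions[s.peptide_id].to_csv(
            out_dir / f"{safe}.truth.tsv", sep="\t"
        )
    rows = []
    for pid, ids in truth.group_specific.items():
        for cid in ids:
            rows.append(
                {"peptide_id": pid, "channel_id": cid,
                 "mz": truth.channel_mz[pid][cid]}
            )
    pd.DataFrame(rows).to_csv(out_dir / "diagnostics.tsv", sep="\t", index=False)
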