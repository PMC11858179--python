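"""Theoretical fragment-ion enumeration.

Covers the three ion families needed to rationalise arginine-rich peptide
CID spectra:

* conventional b/y backbone fragments (b_i counts i residues from the
  N-terminus, y_j counts j from the C-terminus, 1-based; b_n — the
  water-deficient full-length ion — is included because it is routinely
  observed for these peptides),
* combinatorial neutral-loss series (consecutive losses of ammonia, water,
  carbodiimide, and guanidine),
* scrambled b ions: the full-length b ion cyclises head-to-tail and reopens
  at any amide bond, so every contiguous substring of the *cyclic* sequence
  becomes a candidate b-type fragment.  Full-length rotations are kind
  ``scrambled_b``; shorter spans are ``internal_b`` with provenance
  recording (start, length).

The scrambling model is purely combinatorial (all cyclic reopenings), not
energetic; it must merely contain every pathway an experiment can realise.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .masses import (
    IonKind,
    IonSpec,
    NeutralLoss,
    PeptideSequence,
    ResidueTable,
    default_losses,
    ion_mz,
)

__all__ = [
    "CatalogueConfig",
    "FragmentCatalogue",
    "enumerate_conventional",
    "enumerate_loss_series",
    "enumerate_scrambled",
    "build_catalogue",
]


def enumerate_conventional(
    seq: PeptideSequence, max_charge: int
) -> list[IonSpec]:
    """All b_1..b_n and y_1..y_{n-1} ions at charges 1..max_charge,
    plus the intact precursor at each charge."""
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")
    n = len(seq)
    ions: list[IonSpec] = []
    for z in range(1, max_charge + 1):
        ions.append(IonSpec(IonKind.PRECURSOR, seq.residues, z))
        for i in range(1, n + 1):  # b_1 .. b_n
            ions.append(
                IonSpec(IonKind.B, seq.residues[:i], z, provenance=f"b{i}")
            )
        for j in range(1, n):  # y_1 .. y_{n-1}
            ions.append(
                IonSpec(IonKind.Y, seq.residues[n - j :], z, provenance=f"y{j}")
            )
    return ions


def enumerate_loss_series(
    base: IonSpec,
    catalogue: Sequence[NeutralLoss],
    max_total: int,
    caps: Mapping[str, int] | None = None,
) -> list[IonSpec]:
    """Combine ``base`` with every multiset of 1..max_total neutral losses
    from ``catalogue``, respecting per-loss caps (exceeding a cap silently
    excludes the combination).  Non-physical combinations (losses exceeding
    the fragment mass) are excluded likewise."""
    if max_total < 0:
        raise ValueError("max_total must be >= 0")
    caps = dict(caps or {})
    losses = sorted(set(catalogue))
    existing = {l.name: sum(1 for x in base.losses if x.name == l.name) for l in losses}

    out: list[IonSpec] = []

    # depth-first over loss multisets; each combination appended once
    def rec_multi(idx: int, remaining: int, chosen: list[NeutralLoss]) -> None:
        if chosen:
            out.append(base.with_losses(*chosen))
        if remaining == 0:
            return
        for i in range(idx, len(losses)):
            l = losses[i]
            used = existing.get(l.name, 0) + sum(1 for x in chosen if x.name == l.name)
            if l.name in caps and used + 1 > caps[l.name]:
                continue
            chosen.append(l)
            rec_multi(i, remaining - 1, chosen)
            chosen.pop()

    rec_multi(0, max_total, [])

    # drop non-physical combinations
    physical = []
    for ion in out:
        try:
            ion_mz(ion)
        except ValueError:
            continue
        physical.append(ion)
    return physical


def enumerate_scrambled(
    seq: PeptideSequence, max_charge: int, min_length: int = 1
) -> list[IonSpec]:
    """b-type ions from macrocycle reopening: every contiguous substring of
    the cyclic residue sequence, for every start 0..n-1 and length
    min_length..n, at charges 1..max_charge."""
    n = len(seq)
    if n < 3:
        raise ValueError("scrambling needs a sequence of length >= 3")
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    doubled = seq.residues + seq.residues
    ions: list[IonSpec] = []
    for start in range(n):
        for length in range(min_length, n + 1):
            content = doubled[start : start + length]
            kind = IonKind.SCRAMBLED_B if length == n else IonKind.INTERNAL_B
            for z in range(1, max_charge + 1):
                ions.append(
                    IonSpec(
                        kind,
                        content,
                        z,
                        provenance=f"cyclic(start={start},length={length})",
                    )
                )
    return ions


@dataclass(frozen=True)
class CatalogueConfig:
    """Generation parameters for a fragment catalogue.

    Loss caps default to ammonia <= 4 and water <= 2; carbodiimide and
    guanidine are capped at the arginine count of each ion (they originate
    from arginine side-chain termini, so an ion cannot shed more of them
    than it has arginines).
    """

    max_charge: int = 2
    max_total_losses: int = 4
    ammonia_cap: int = 4
    water_cap: int = 2
    scrambling: bool = True
    internal_ions: bool = True
    min_internal_length: int = 2

    def caps_for(self, ion: IonSpec) -> dict[str, int]:
        n_arg = sum(1 for c in ion.residues if c == "R")
        return {
            "ammonia": self.ammonia_cap,
            "water": self.water_cap,
            "carbodiimide": n_arg,
            "guanidine": n_arg,
        }


@dataclass
class FragmentCatalogue:
    """Deduplicated, m/z-sorted theoretical ions for one peptide."""

    peptide: PeptideSequence
    ions: list[IonSpec]
    mzs: list[float]
    config: CatalogueConfig = _field(default_factory=CatalogueConfig)

    def __len__(self) -> int:
        return len(self.ions)

    def to_dataframe(self) -> pd.DataFrame:
        from .annotate import format_label  # deferred: annotate imports us

        rows = []
        for ion, mz in zip(self.ions, self.mzs):
            rows.append(
                {
                    "label": format_label(ion),
                    "kind": ion.kind.value,
                    "charge": ion.charge,
                    "losses": ";".join(l.name for l in ion.losses),
                    "mz": mz,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def build_catalogue(
    seq: PeptideSequence,
    config: CatalogueConfig | None = None,
    table: ResidueTable | None = None,
    losses: Iterable[NeutralLoss] | None = None,
) -> FragmentCatalogue:
    """Union of conventional, scrambled (if enabled), and loss-series ions,
    deduplicated by (kind, residue composition, charge, losses) and sorted
    by m/z.  Mass-identical cyclic rotations collapse to one entry; their
    origin stays readable via provenance."""
    config = config or CatalogueConfig()
    table = table if table is not None else ResidueTable.default()
    loss_cat = list(losses) if losses is not None else list(default_losses().values())

    bases: list[IonSpec] = enumerate_conventional(seq, config.max_charge)
    if config.scrambling:
        scr = enumerate_scrambled(
            seq, config.max_charge, min_length=config.min_internal_length
        )
        if not config.internal_ions:
            scr = [i for i in scr if i.kind is IonKind.SCRAMBLED_B]
        bases.extend(scr)

    all_ions: list[IonSpec] = []
    seen: set = set()
    for base in bases:
        for ion in [base] + enumerate_loss_series(
            base, loss_cat, config.max_total_losses, config.caps_for(base)
        ):
            key = ion.dedup_key()
            if key in seen:
                continue
            seen.add(key)
            all_ions.append(ion)

    pairs = []
    for ion in all_ions:
        try:
            mz = ion_mz(ion, table)
        except ValueError:
            continue
        pairs.append((mz, ion))
    pairs.sort(key=lambda p: p[0])
    return FragmentCatalogue(
        peptide=seq,
        ions=[p[1] for p in pairs],
        mzs=[p[0] for p in pairs],
        config=config,
    )
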