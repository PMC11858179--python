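"""Matching observed peaks against a theoretical fragment catalogue.

Each peak is assigned the catalogue candidate minimising |delta m/z| within
a tolerance (absolute Th or ppm).  When candidates are equidistant the
least exotic explanation wins: fewer total neutral losses, then
conventional > internal > scrambled kind, then lower charge.  Equidistance
is judged with a 1e-6 Th epsilon because distinct ions can be *exactly*
mass-degenerate (different residue/loss bookkeeping, identical elemental
composition) and float summation order must not decide between them.

Labels follow a compact round-trippable grammar::

    [M+2H-NH3]2+      precursor minus ammonia, doubly charged
    [b10-CH2N2]2+     conventional b ion minus carbodiimide
    [y12-H2O-NH3]2+   y ion with two losses
    [int(RRRP)]+      internal b-type ion (two backbone cleavages)
    [scr(RRRPS...)]2+ full-length scrambled (cyclised/reopened) b ion
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragments import FragmentCatalogue
from .masses import IonKind, IonSpec
from .spectra import Spectrum

__all__ = [
    "format_label",
    "parse_label",
    "Annotation",
    "annotate_spectrum",
    "diagnostic_table",
]

#: equidistance epsilon for tie-breaking (Th).  Candidates this close are
#: physically indistinguishable at any realistic resolution; the margin also
#: absorbs the <=6.5e-5 Da gap between catalogued (printed) neutral-loss
#: masses and their exact formula masses, so elemental degeneracies (e.g.
#: CH5N3 vs CH2N2+NH3) are treated as true ties.
TIE_EPS = 1e-4

_KIND_PRIORITY = {
    IonKind.PRECURSOR: 0,
    IonKind.B: 0,
    IonKind.Y: 0,
    IonKind.INTERNAL_B: 1,
    IonKind.SCRAMBLED_B: 2,
}


def _seq_text(residues: tuple[str, ...]) -> str:
    return "".join(c if len(c) == 1 else f"[{c}]" for c in residues)


def format_label(ion: IonSpec) -> str:
    """Render an ion as text, e.g. ``[y12-H2O-NH3]2+``."""
    if ion.kind is IonKind.PRECURSOR:
        base = f"M+{ion.charge}H"
    elif ion.kind is IonKind.B:
        base = f"b{len(ion.residues)}"
    elif ion.kind is IonKind.Y:
        base = f"y{len(ion.residues)}"
    elif ion.kind is IonKind.INTERNAL_B:
        base = f"int({_seq_text(ion.residues)})"
    else:
        base = f"scr({_seq_text(ion.residues)})"
    counts: dict[str, int] = {}
    for l in ion.losses:
        counts[l.formula] = counts.get(l.formula, 0) + 1
    loss_txt = "".join(
        f"-{n if n > 1 else ''}{f}" for f, n in sorted(counts.items())
    )
    z_txt = f"{ion.charge}+" if ion.charge > 1 else "+"
    return f"[{base}{loss_txt}]{z_txt}"


_LABEL_RE = re.compile(
    r"^\[(?P<base>M\+\d+H|b\d+|y\d+|int\([^)]*\)|scr\([^)]*\))"
    r"(?P<losses>(?:-\d*[A-Za-z0-9]+)*)\]"
    r"(?P<charge>\d*)\+$"
)
_LOSS_RE = re.compile(r"-(\d*)([A-Za-z][A-Za-z0-9]*)")


def parse_label(label: str) -> dict:
    """Invert :func:`format_label`: returns kind, base content descriptor,
    charge, and loss-formula counts."""
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"cannot parse ion label {label!r}")
    base = m.group("base")
    charge = int(m.group("charge") or 1)
    losses: dict[str, int] = {}
    for n, f in _LOSS_RE.findall(m.group("losses")):
        losses[f] = losses.get(f, 0) + int(n or 1)
    if base.startswith("M+"):
        kind, content = IonKind.PRECURSOR, base
    elif base.startswith("int("):
        kind, content = IonKind.INTERNAL_B, base[4:-1]
    elif base.startswith("scr("):
        kind, content = IonKind.SCRAMBLED_B, base[4:-1]
    elif base[0] == "b":
        kind, content = IonKind.B, base
    else:
        kind, content = IonKind.Y, base
    return {"kind": kind, "content": content, "charge": charge, "losses": losses}


@dataclass(frozen=True)
class Annotation:
    observed_mz: float
    ion: IonSpec
    theoretical_mz: float
    error_mth: float  # observed - theoretical, in milli-Th
    error_ppm: float
    label: str


def _tie_key(ion: IonSpec) -> tuple:
    return (len(ion.losses), _KIND_PRIORITY[ion.kind], ion.charge)


def annotate_spectrum(
    s: Spectrum,
    cat: FragmentCatalogue,
    tol_mode: str = "absolute",
    tol: float = 0.02,
    exhaustive: bool = False,
) -> list[Annotation]:
    """Annotate every peak with its best catalogue match within tolerance.

    With ``exhaustive=True`` every candidate within tolerance is returned
    per peak instead of only the best one.  Unmatched peaks are omitted.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if tol_mode not in ("absolute", "ppm"):
        raise ValueError("tol_mode must be 'absolute' or 'ppm'")
    cat_mzs = np.asarray(cat.mzs)
    out: list[Annotation] = []
    for mz_obs in s.mz:
        tol_th = tol if tol_mode == "absolute" else tol * 1e-6 * mz_obs
        lo = int(np.searchsorted(cat_mzs, mz_obs - tol_th, side="left"))
        hi = int(np.searchsorted(cat_mzs, mz_obs + tol_th, side="right"))
        if lo == hi:
            continue
        candidates = [
            (abs(cat_mzs[i] - mz_obs), i) for i in range(lo, hi)
        ]
        if exhaustive:
            chosen = [i for _, i in sorted(candidates)]
        else:
            best_d = min(d for d, _ in candidates)
            tied = [i for d, i in candidates if d <= best_d + TIE_EPS]
            chosen = [min(tied, key=lambda i: _tie_key(cat.ions[i]))]
        for i in chosen:
            ion = cat.ions[i]
            mz_theo = float(cat_mzs[i])
            out.append(
                Annotation(
                    observed_mz=float(mz_obs),
                    ion=ion,
                    theoretical_mz=mz_theo,
                    error_mth=(mz_obs - mz_theo) * 1e3,
                    error_ppm=(mz_obs - mz_theo) / mz_theo * 1e6,
                    label=format_label(ion),
                )
            )
    return out


def diagnostic_table(
    report,
    annotations_per_group: dict[str, list[Annotation]],
    top_k: int | None = None,
    tol: float = 0.02,
) -> pd.DataFrame:
    """Join PCA-ranked diagnostic m/z variables with structural annotations.

    One row per (group, diagnostic variable); variables with no annotation
    within ``tol`` are reported as ``unassigned`` — a diagnostic peak
    without a structural hypothesis is still a usable marker.
    """
    rows = []
    for group, table in report.tables.items():
        anns = annotations_per_group.get(group, [])
        sub = table if top_k is None else table.head(top_k)
        for _, r in sub.iterrows():
            label = "unassigned"
            best = tol
            for a in anns:
                d = abs(a.observed_mz - r["mz"])
                if d <= best:
                    best = d
                    label = a.label
            rows.append(
                {
                    "group": group,
                    "mz": r["mz"],
                    "loading_magnitude": r["loading_magnitude"],
                    "specificity": r["specificity"],
                    "score": r["score"],
                    "annotation": label,
                }
            )
    return pd.DataFrame(rows)
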