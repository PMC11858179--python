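"""Reading, preprocessing, and aligning energy-resolved MS/MS spectra.

A :class:`Spectrum` is a centroided peak list tagged with the metadata the
energy-resolved workflow needs: peptide identity, acceleration voltage,
replicate, and precursor definition.  A :class:`SpectrumSeries` collects one
peptide's spectra across the voltage ramp.  :func:`align_to_matrix` turns a
set of spectra into the samples x m/z-variables matrix that PCA consumes,
clustering peaks across spectra by single linkage within a tolerance.

Supported formats: MGF (one scan per voltage, metadata as ``key=value``
tokens in TITLE), mzML (voltage from the standard collision-energy
attribute), and two-column delimited peak lists with a per-directory
``metadata.tsv`` sidecar.  Metadata that cannot be recovered is an error,
never a silent default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "SpectrumMeta",
    "Spectrum",
    "SpectrumSeries",
    "read_spectra",
    "write_mgf",
    "smooth_and_centroid",
    "tic_normalize",
    "AlignedMatrix",
    "align_to_matrix",
]


@dataclass(frozen=True)
class SpectrumMeta:
    peptide_id: str
    voltage: float
    replicate: int
    precursor_mz: float
    precursor_charge: int


@dataclass
class Spectrum:
    """A centroided peak list (m/z ascending, intensities >= 0)."""

    mz: np.ndarray
    intensity: np.ndarray
    meta: SpectrumMeta

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class SpectrumSeries:
    """All spectra of one peptide across voltages/replicates."""

    spectra: list[Spectrum]

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValueError("series must contain at least one spectrum")
        ids = {s.meta.peptide_id for s in self.spectra}
        if len(ids) != 1:
            raise ValueError(f"series mixes peptide ids: {sorted(ids)}")
        prec = {(s.meta.precursor_mz, s.meta.precursor_charge) for s in self.spectra}
        if len(prec) != 1:
            raise ValueError("series mixes precursor definitions")

    @property
    def peptide_id(self) -> str:
        return self.spectra[0].meta.peptide_id

    @property
    def precursor_mz(self) -> float:
        return self.spectra[0].meta.precursor_mz

    @property
    def voltages(self) -> list[float]:
        return sorted({s.meta.voltage for s in self.spectra})

    def at_voltage(self, voltage: float) -> list[Spectrum]:
        return [s for s in self.spectra if s.meta.voltage == voltage]


# ---------------------------------------------------------------------------
# reading / writing


def _meta_from_title(title: str) -> dict[str, str]:
    tokens = {}
    for tok in title.split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            tokens[k.lower()] = v
    return tokens


def _read_mgf(path: Path) -> list[Spectrum]:
    from pyteomics import mgf

    spectra = []
    with mgf.read(str(path)) as reader:
        for rec in reader:
            params = rec["params"]
            title = params.get("title", "")
            tokens = _meta_from_title(title)
            missing = [k for k in ("peptide", "voltage", "replicate") if k not in tokens]
            if missing:
                raise ValueError(
                    f"{path}: scan TITLE {title!r} lacks metadata fields {missing}"
                )
            if "pepmass" not in params:
                raise ValueError(f"{path}: scan {title!r} lacks PEPMASS")
            if "charge" not in params:
                raise ValueError(f"{path}: scan {title!r} lacks CHARGE")
            meta = SpectrumMeta(
                peptide_id=tokens["peptide"],
                voltage=float(tokens["voltage"]),
                replicate=int(tokens["replicate"]),
                precursor_mz=float(params["pepmass"][0]),
                precursor_charge=int(params["charge"][0]),
            )
            spectra.append(Spectrum(rec["m/z array"], rec["intensity array"], meta))
    return spectra


def _decode_binary_array(elem, ns: str) -> np.ndarray:
    """Decode one mzML binaryDataArray (64/32-bit float, optional zlib)."""
    import base64
    import zlib

    accessions = {
        cv.get("accession") for cv in elem.findall(f"{ns}cvParam")
    }
    dtype = np.float32 if "MS:1000521" in accessions else np.float64
    node = elem.find(f"{ns}binary")
    raw = base64.b64decode(node.text or "")
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: Path) -> list[Spectrum]:
    # direct lxml parsing: the pyteomics mzML backend needs an extra
    # package for controlled-vocabulary handling, and only a narrow slice
    # of the standard is needed here
    from lxml import etree

    tree = etree.parse(str(path))
    root = tree.getroot()
    ns = "{%s}" % root.nsmap.get(None) if root.nsmap.get(None) else ""

    def cv_value(parent, accession):
        for cv in parent.findall(f"{ns}cvParam"):
            if cv.get("accession") == accession or cv.get("name") == accession:
                return cv.get("value")
        return None

    spectra = []
    for i, spec in enumerate(root.iter(f"{ns}spectrum")):
        precursor = spec.find(f"{ns}precursorList/{ns}precursor")
        activation = None if precursor is None else precursor.find(f"{ns}activation")
        voltage = None if activation is None else cv_value(activation, "MS:1000045")
        if voltage is None:
            raise ValueError(
                f"{path}: spectrum {i} lacks the collision-energy annotation "
                "required for energy-resolved analysis"
            )
        sel = precursor.find(f"{ns}selectedIonList/{ns}selectedIon")
        prec_mz = None if sel is None else cv_value(sel, "MS:1000744")
        charge = None if sel is None else cv_value(sel, "MS:1000041")
        if prec_mz is None or charge is None:
            raise ValueError(
                f"{path}: spectrum {i} lacks selected-ion m/z or charge state"
            )
        tokens = _meta_from_title(spec.get("id", ""))
        peptide = tokens.get("peptide")
        if peptide is None:
            raise ValueError(
                f"{path}: spectrum {i} lacks a 'peptide=<id>' token in its id"
            )
        arrays: dict[str, np.ndarray] = {}
        for bda in spec.iter(f"{ns}binaryDataArray"):
            accs = {cv.get("accession") for cv in bda.findall(f"{ns}cvParam")}
            data = _decode_binary_array(bda, ns)
            if "MS:1000514" in accs:
                arrays["mz"] = data
            elif "MS:1000515" in accs:
                arrays["intensity"] = data
        if "mz" not in arrays or "intensity" not in arrays:
            raise ValueError(f"{path}: spectrum {i} lacks m/z or intensity array")
        meta = SpectrumMeta(
            peptide_id=peptide,
            voltage=float(voltage),
            replicate=int(tokens.get("replicate", 1)),
            precursor_mz=float(prec_mz),
            precursor_charge=int(charge),
        )
        spectra.append(Spectrum(arrays["mz"], arrays["intensity"], meta))
    return spectra


def _read_csv(path: Path) -> list[Spectrum]:
    sidecar = path.parent / "metadata.tsv"
    if not sidecar.exists():
        raise ValueError(
            f"{path}: delimited peak lists need a metadata.tsv sidecar in the "
            "same directory (columns: file, peptide_id, voltage, replicate, "
            "precursor_mz, precursor_charge)"
        )
    meta_df = pd.read_csv(sidecar, sep="\t")
    required = {"file", "peptide_id", "voltage", "replicate", "precursor_mz", "precursor_charge"}
    if not required.issubset(meta_df.columns):
        raise ValueError(f"{sidecar}: missing columns {sorted(required - set(meta_df.columns))}")
    row = meta_df[meta_df["file"] == path.name]
    if len(row) != 1:
        raise ValueError(f"{sidecar}: expected exactly one row for {path.name}, found {len(row)}")
    row = row.iloc[0]
    peaks = pd.read_csv(path)
    if list(peaks.columns[:2]) != ["mz", "intensity"]:
        raise ValueError(f"{path}: peak list must have header columns 'mz,intensity'")
    meta = SpectrumMeta(
        peptide_id=str(row["peptide_id"]),
        voltage=float(row["voltage"]),
        replicate=int(row["replicate"]),
        precursor_mz=float(row["precursor_mz"]),
        precursor_charge=int(row["precursor_charge"]),
    )
    return [Spectrum(peaks["mz"].to_numpy(), peaks["intensity"].to_numpy(), meta)]


def read_spectra(path: str | Path, format: str | None = None) -> list[Spectrum]:
    """Read spectra from MGF, mzML, or CSV peak lists.  ``format`` is
    inferred from the suffix when not given."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".mgf": "mgf", ".mzml": "mzml", ".csv": "csv"}.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format from suffix of {path}")
    if format == "mgf":
        return _read_mgf(path)
    if format == "mzml":
        return _read_mzml(path)
    if format == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown format {format!r}")


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF with metadata encoded in TITLE tokens."""
    from pyteomics import mgf

    records = []
    for s in spectra:
        records.append(
            {
                "m/z array": s.mz,
                "intensity array": s.intensity,
                "params": {
                    "title": (
                        f"peptide={s.meta.peptide_id} voltage={s.meta.voltage:g} "
                        f"replicate={s.meta.replicate}"
                    ),
                    "pepmass": s.meta.precursor_mz,
                    "charge": s.meta.precursor_charge,
                },
            }
        )
    mgf.write(records, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# preprocessing


def smooth_and_centroid(
    mz: np.ndarray,
    intensity: np.ndarray,
    meta: SpectrumMeta,
    window: int = 5,
    polyorder: int = 2,
    min_intensity: float = 0.01,
) -> Spectrum:
    """Savitzky-Golay smoothing followed by local-maximum centroiding of a
    profile-mode spectrum.

    Each local maximum above ``min_intensity`` x base peak claims its
    contiguous above-threshold region up to the neighbouring local minima;
    the peak m/z is the intensity-weighted centroid of that region and its
    intensity the region sum.
    """
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window < polyorder + 2:
        raise ValueError("window must be >= polyorder + 2")
    if len(mz) < window:
        raise ValueError(f"profile has {len(mz)} points, fewer than window={window}")
    smooth = savgol_filter(intensity, window, polyorder)
    smooth = np.clip(smooth, 0.0, None)
    if smooth.max() <= 0:
        return Spectrum(np.empty(0), np.empty(0), meta)
    threshold = min_intensity * smooth.max()

    peaks_mz: list[float] = []
    peaks_int: list[float] = []
    n = len(smooth)
    i = 1
    while i < n - 1:
        if smooth[i] >= threshold and smooth[i] >= smooth[i - 1] and smooth[i] > smooth[i + 1]:
            lo = i
            while lo > 0 and threshold <= smooth[lo - 1] <= smooth[lo]:
                lo -= 1
            hi = i
            while hi < n - 1 and threshold <= smooth[hi + 1] <= smooth[hi]:
                hi += 1
            seg_i = smooth[lo : hi + 1]
            seg_m = mz[lo : hi + 1]
            area = seg_i.sum()
            if area > 0:
                peaks_mz.append(float((seg_m * seg_i).sum() / area))
                peaks_int.append(float(area))
            i = hi + 1
        else:
            i += 1
    return Spectrum(np.array(peaks_mz), np.array(peaks_int), meta)


def tic_normalize(s: Spectrum) -> Spectrum:
    """Divide intensities by their sum (total ion current); output sums to 1."""
    total = s.tic
    if total <= 0:
        raise ValueError("cannot TIC-normalise an all-zero spectrum")
    return Spectrum(s.mz.copy(), s.intensity / total, s.meta)


# ---------------------------------------------------------------------------
# alignment


@dataclass
class AlignedMatrix:
    """Samples x m/z-variables intensity matrix with per-row metadata."""

    variable_mzs: np.ndarray
    X: np.ndarray
    metas: list[SpectrumMeta]
    tic_normalized: bool = False

    def __post_init__(self) -> None:
        self.variable_mzs = np.asarray(self.variable_mzs, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.metas), len(self.variable_mzs)):
            raise ValueError("matrix shape does not match metadata/variables")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=[f"{m:.4f}" for m in self.variable_mzs])
        df.insert(0, "peptide_id", [m.peptide_id for m in self.metas])
        df.insert(1, "voltage", [m.voltage for m in self.metas])
        df.insert(2, "replicate", [m.replicate for m in self.metas])
        return df


def align_to_matrix(
    spectra: Sequence[Spectrum],
    mz_range: tuple[float, float] = (0.0, np.inf),
    tol: float = 0.02,
) -> AlignedMatrix:
    """Cluster peaks across spectra into consensus m/z variables by single
    linkage within ``tol`` (in 1-D this is exactly: split the sorted peak
    list wherever the gap between neighbours exceeds ``tol``).  Variable
    m/z is the intensity-weighted mean of cluster members; each spectrum
    contributes its summed intensity per variable.  Peaks outside
    ``mz_range`` are discarded."""
    if tol <= 0:
        raise ValueError("tol must be > 0")
    lo, hi = mz_range
    if not lo < hi:
        raise ValueError("mz_range must satisfy lo < hi")

    all_mz: list[float] = []
    all_int: list[float] = []
    all_idx: list[int] = []
    for i, s in enumerate(spectra):
        keep = (s.mz >= lo) & (s.mz <= hi)
        all_mz.extend(s.mz[keep])
        all_int.extend(s.intensity[keep])
        all_idx.extend([i] * int(keep.sum()))

    normalized = bool(spectra) and all(abs(s.tic - 1.0) <= 1e-9 for s in spectra)
    if not all_mz:
        return AlignedMatrix(
            np.empty(0), np.zeros((len(spectra), 0)),
            [s.meta for s in spectra], normalized,
        )

    mz_arr = np.array(all_mz)
    int_arr = np.array(all_int)
    idx_arr = np.array(all_idx)
    order = np.argsort(mz_arr, kind="stable")
    mz_arr, int_arr, idx_arr = mz_arr[order], int_arr[order], idx_arr[order]

    breaks = np.nonzero(np.diff(mz_arr) > tol)[0] + 1
    bounds = np.concatenate(([0], breaks, [len(mz_arr)]))

    var_mzs = []
    X = np.zeros((len(spectra), len(bounds) - 1))
    for v, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        seg_int = int_arr[a:b]
        seg_mz = mz_arr[a:b]
        w = seg_int.sum()
        var_mzs.append(float((seg_mz * seg_int).sum() / w) if w > 0 else float(seg_mz.mean()))
        np.add.at(X, (idx_arr[a:b], v), seg_int)
    return AlignedMatrix(np.array(var_mzs), X, [s.meta for s in spectra], normalized)
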