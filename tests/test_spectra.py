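"""Spectrum IO, centroiding, TIC normalisation, and peak alignment."""

import numpy as np
import pytest

from isofrag.spectra import (
    Spectrum,
    SpectrumMeta,
    align_to_matrix,
    read_spectra,
    smooth_and_centroid,
    tic_normalize,
    write_mgf,
)


def make_meta(peptide="Car-TAT1", voltage=36.0, replicate=1):
    return SpectrumMeta(peptide, voltage, replicate, 895.04, 2)


def make_spectrum(mz, intensity, **kw):
    return Spectrum(np.asarray(mz, float), np.asarray(intensity, float), make_meta(**kw))


class TestSpectrumContainer:
    def test_peaks_sorted_on_construction(self):
        s = make_spectrum([300.0, 100.0, 200.0], [3.0, 1.0, 2.0])
        assert list(s.mz) == [100.0, 200.0, 300.0]
        assert list(s.intensity) == [1.0, 2.0, 3.0]

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            make_spectrum([100.0], [-1.0])

    def test_series_rejects_mixed_peptides(self):
        from isofrag.spectra import SpectrumSeries

        a = make_spectrum([100.0], [1.0], peptide="A")
        b = make_spectrum([100.0], [1.0], peptide="B")
        with pytest.raises(ValueError, match="mixes"):
            SpectrumSeries([a, b])


class TestMgf:
    def test_round_trip(self, tmp_path):
        spectra = [
            make_spectrum([100.0, 200.5], [10.0, 20.0], voltage=20.0, replicate=1),
            make_spectrum([150.0], [5.0], voltage=22.0, replicate=1),
        ]
        path = tmp_path / "two.mgf"
        write_mgf(spectra, path)
        back = read_spectra(path)
        assert len(back) == 2
        assert back[0].meta.voltage == 20.0
        assert back[0].meta.peptide_id == "Car-TAT1"
        assert back[0].meta.precursor_charge == 2
        np.testing.assert_allclose(back[0].mz, [100.0, 200.5])

    def test_missing_voltage_is_error(self, tmp_path):
        path = tmp_path / "bad.mgf"
        path.write_text(
            "BEGIN IONS\nTITLE=peptide=X replicate=1\nPEPMASS=895.04\n"
            "CHARGE=2+\n100.0 1.0\nEND IONS\n"
        )
        with pytest.raises(ValueError, match="voltage"):
            read_spectra(path)


class TestCsv:
    def test_with_sidecar(self, tmp_path):
        (tmp_path / "scan1.csv").write_text("mz,intensity\n100.0,5.0\n200.0,10.0\n")
        (tmp_path / "metadata.tsv").write_text(
            "file\tpeptide_id\tvoltage\treplicate\tprecursor_mz\tprecursor_charge\n"
            "scan1.csv\tT-Car-T\t36\t2\t895.04\t2\n"
        )
        (s,) = read_spectra(tmp_path / "scan1.csv")
        assert s.meta.peptide_id == "T-Car-T"
        assert s.meta.voltage == 36.0
        assert s.meta.replicate == 2
        assert len(s) == 2

    def test_missing_sidecar_is_error(self, tmp_path):
        (tmp_path / "scan1.csv").write_text("mz,intensity\n100.0,5.0\n")
        with pytest.raises(ValueError, match="metadata.tsv"):
            read_spectra(tmp_path / "scan1.csv")


_MZML_TEMPLATE = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="r">
    <spectrumList count="1">
      <spectrum index="0" id="scan=1 peptide=T-Car-T replicate=1" defaultArrayLength="2">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>
        <precursorList count="1">
          <precursor>
            <selectedIonList count="1">
              <selectedIon>
                <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="895.04"/>
                <cvParam cvRef="MS" accession="MS:1000041" name="charge state" value="2"/>
              </selectedIon>
            </selectedIonList>
            <activation>
{activation}
            </activation>
          </precursor>
        </precursorList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
    </spectrumList>
  </run>
</mzML>
"""


def _write_mzml(path, with_ce: bool):
    import base64

    mz = np.array([100.0, 200.0]).tobytes()
    inten = np.array([1.0, 2.0]).tobytes()
    activation = (
        '<cvParam cvRef="MS" accession="MS:1000045" name="collision energy" '
        'value="36.0" unitName="electronvolt"/>'
        if with_ce
        else '<cvParam cvRef="MS" accession="MS:1000133" '
        'name="collision-induced dissociation" value=""/>'
    )
    mz_b64 = base64.b64encode(mz).decode()
    int_b64 = base64.b64encode(inten).decode()
    path.write_text(
        _MZML_TEMPLATE.format(
            activation=activation,
            mz_b64=mz_b64,
            int_b64=int_b64,
            mz_len=len(mz_b64),
            int_len=len(int_b64),
        )
    )


class TestMzml:
    def test_reads_collision_energy(self, tmp_path):
        path = tmp_path / "ok.mzml"
        _write_mzml(path, with_ce=True)
        (s,) = read_spectra(path)
        assert s.meta.voltage == 36.0
        assert s.meta.peptide_id == "T-Car-T"
        np.testing.assert_allclose(s.mz, [100.0, 200.0])

    def test_missing_collision_energy_is_error(self, tmp_path):
        path = tmp_path / "no_ce.mzml"
        _write_mzml(path, with_ce=False)
        with pytest.raises(ValueError, match="collision-energy"):
            read_spectra(path)


def gaussian_profile(centres, heights, sigma=0.02, spacing=0.01, span=0.3):
    lo = min(centres) - span
    hi = max(centres) + span
    mz = np.arange(lo, hi, spacing)
    intensity = np.zeros_like(mz)
    for c, h in zip(centres, heights):
        intensity += h * np.exp(-0.5 * ((mz - c) / sigma) ** 2)
    return mz, intensity


class TestCentroiding:
    def test_symmetric_peak_is_unbiased(self):
        mz, inten = gaussian_profile([895.040], [1000.0])
        s = smooth_and_centroid(mz, inten, make_meta())
        assert len(s) == 1
        assert abs(s.mz[0] - 895.040) < 0.005

    def test_flat_zero_profile_gives_empty_spectrum(self):
        mz = np.linspace(100, 101, 50)
        s = smooth_and_centroid(mz, np.zeros_like(mz), make_meta())
        assert len(s) == 0

    def test_resolves_half_thomson_doublet(self):
        """Peaks 0.5 Th apart (the H2O-vs-NH3 signature on 2+ ions) must
        come out as two centroids at instrument-like widths."""
        mz, inten = gaussian_profile([886.03, 886.53], [800.0, 1000.0])
        s = smooth_and_centroid(mz, inten, make_meta())
        assert len(s) == 2
        assert abs(s.mz[0] - 886.03) < 0.01
        assert abs(s.mz[1] - 886.53) < 0.01

    def test_window_validation(self):
        mz, inten = gaussian_profile([500.0], [10.0])
        with pytest.raises(ValueError):
            smooth_and_centroid(mz, inten, make_meta(), window=4)
        with pytest.raises(ValueError):
            smooth_and_centroid(mz[:3], inten[:3], make_meta(), window=5)


class TestTicNormalize:
    def test_simple_fractions(self):
        s = tic_normalize(make_spectrum([100.0, 200.0], [2.0, 8.0]))
        np.testing.assert_allclose(s.intensity, [0.2, 0.8])

    def test_idempotent_and_ratio_preserving(self):
        s = make_spectrum([1.0, 2.0, 3.0], [3.0, 6.0, 1.0])
        once = tic_normalize(s)
        twice = tic_normalize(once)
        np.testing.assert_allclose(once.intensity, twice.intensity, atol=1e-12)
        np.testing.assert_allclose(
            once.intensity[1] / once.intensity[0],
            s.intensity[1] / s.intensity[0],
            rtol=1e-12,
        )

    def test_single_peak(self):
        s = tic_normalize(make_spectrum([100.0], [42.0]))
        assert s.intensity[0] == 1.0

    def test_zero_spectrum_is_error(self):
        with pytest.raises(ValueError):
            tic_normalize(make_spectrum([100.0], [0.0]))


class TestAlign:
    def test_close_peaks_merge_within_tol(self):
        a = make_spectrum([886.52], [1.0], replicate=1)
        b = make_spectrum([886.53], [2.0], replicate=2)
        m = align_to_matrix([a, b], tol=0.02)
        assert len(m.variable_mzs) == 1
        # intensity-weighted consensus m/z
        assert m.variable_mzs[0] == pytest.approx((886.52 + 2 * 886.53) / 3)

    def test_separated_peaks_stay_apart(self):
        a = make_spectrum([886.52], [1.0], replicate=1)
        b = make_spectrum([886.53], [2.0], replicate=2)
        m = align_to_matrix([a, b], tol=0.005)
        assert len(m.variable_mzs) == 2

    def test_range_filter(self):
        a = make_spectrum([650.0, 886.53], [1.0, 5.0])
        m = align_to_matrix([a], mz_range=(600.0, 800.0))
        assert list(m.variable_mzs) == [650.0]

    def test_row_sums_conserve_in_range_intensity(self, scenario_run):
        series, _ = scenario_run
        spectra = series[0].spectra[:6]
        m = align_to_matrix(spectra, mz_range=(600.0, 900.0), tol=0.02)
        for i, s in enumerate(spectra):
            keep = (s.mz >= 600.0) & (s.mz <= 900.0)
            assert m.X[i].sum() == pytest.approx(s.intensity[keep].sum(), rel=1e-9)

    def test_normalisation_flag(self):
        raw = make_spectrum([100.0, 200.0], [2.0, 8.0])
        assert not align_to_matrix([raw]).tic_normalized
        assert align_to_matrix([tic_normalize(raw)]).tic_normalized
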