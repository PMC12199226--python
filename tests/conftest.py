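"""Shared fixtures: proteins, small simulated studies, and an mzML writer.

All fixture data is generated programmatically; nothing is read from disk
except files the tests themselves write into tmp_path.
"""

from __future__ import annotations

import base64
import struct
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from polysorb.e8 import INSULIN
from polysorb.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def insulin():
    return INSULIN


@pytest.fixture(scope="session")
def small_noiseless_study():
    """Six polymers, triplicate, all noise off — exact-closure territory."""
    return simulate_study(SimulationConfig(n_polymers=6, seed=11).noiseless())


@pytest.fixture(scope="session")
def small_noisy_study():
    """Forty polymers at the default noise level — enough rows for stable
    rank correlations while staying fast."""
    return simulate_study(SimulationConfig(n_polymers=40, seed=23))


def _b64(array: np.ndarray) -> str:
    return base64.b64encode(np.asarray(array, dtype="<f8").tobytes()).decode()


def write_minimal_mzml(path: Path, scans: list[dict]) -> None:
    """Author a tiny centroided mzML file by hand.

    Each scan dict: ms_level, mz (array), intensity (array), and for MS2
    precursor_mz; for MS1 scan_low/scan_high.  64-bit uncompressed arrays.
    """
    spectra_xml = []
    for i, scan in enumerate(scans):
        level = scan["ms_level"]
        mz = np.asarray(scan["mz"], dtype=float)
        inten = np.asarray(scan["intensity"], dtype=float)
        if level == 2:
            extra = f"""
      <precursorList count="1">
        <precursor>
          <isolationWindow>
            <cvParam cvRef="MS" accession="MS:1000828" name="isolation window lower offset" value="0.5"/>
            <cvParam cvRef="MS" accession="MS:1000829" name="isolation window upper offset" value="0.5"/>
          </isolationWindow>
          <selectedIonList count="1">
            <selectedIon>
              <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{scan['precursor_mz']}"/>
            </selectedIon>
          </selectedIonList>
          <activation/>
        </precursor>
      </precursorList>"""
            scan_xml = "<scanList count=\"1\"><scan/></scanList>"
        else:
            extra = ""
            scan_xml = f"""<scanList count="1">
        <scan>
          <scanWindowList count="1">
            <scanWindow>
              <cvParam cvRef="MS" accession="MS:1000501" name="scan window lower limit" value="{scan['scan_low']}"/>
              <cvParam cvRef="MS" accession="MS:1000500" name="scan window upper limit" value="{scan['scan_high']}"/>
            </scanWindow>
          </scanWindowList>
        </scan>
      </scanList>"""
        spectra_xml.append(f"""
    <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{mz.size}">
      <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{level}"/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
      {scan_xml}{extra}
      <binaryDataArrayList count="2">
        <binaryDataArray encodedLength="0">
          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
          <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
          <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
          <binary>{_b64(mz)}</binary>
        </binaryDataArray>
        <binaryDataArray encodedLength="0">
          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
          <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
          <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
          <binary>{_b64(inten)}</binary>
        </binaryDataArray>
      </binaryDataArrayList>
    </spectrum>""")
    body = "".join(spectra_xml)
    path.write_text(f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <fileDescription><fileContent/></fileDescription>
  <softwareList count="0"/>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1"/>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="DP1"><processingMethod order="1" softwareRef="none"/></dataProcessing>
  </dataProcessingList>
  <run id="test_run" defaultInstrumentConfigurationRef="IC1">
    <spectrumList count="{len(scans)}" defaultDataProcessingRef="DP1">{body}
    </spectrumList>
  </run>
</mzML>
""")
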