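"""Minimal synthetic mzML writer for test fixtures.

Writing mzML is out of scope for the package itself; the tests only need a
tiny well-formed file to exercise the reader, so this helper emits the bare
structure (spectrum list, cvParams, base64 float64 arrays) by hand.
"""

from __future__ import annotations

import base64
import struct
from pathlib import Path
from typing import Optional, Sequence

_HEADER = '<?xml version="1.0" encoding="utf-8"?>\n<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n <run id="run0">\n  <spectrumList count="{n}">\n'
_FOOTER = "  </spectrumList>\n </run>\n</mzML>\n"

_MODE_CV = {
    "centroid": '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>',
    "profile": '<cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>',
}

_RT_UNIT = {
    "second": ("UO:0000010", "second"),
    "minute": ("UO:0000031", "minute"),
}


def _b64(values: Sequence[float]) -> str:
    return base64.b64encode(struct.pack(f"<{len(values)}d", *values)).decode()


def write_mzml(
    path: Path,
    spectra: Sequence[dict],
) -> Path:
    """Write a minimal mzML file.

    Each spectrum dict has keys: ``rt`` (float), ``mz`` (list), ``intensity``
    (list), and optionally ``ms_level`` (default 1), ``mode``
    ('centroid'/'profile'/None), ``rt_unit`` ('second'/'minute').
    """
    parts = [_HEADER.format(n=len(spectra))]
    for i, sp in enumerate(spectra):
        ms_level = sp.get("ms_level", 1)
        mode = sp.get("mode")
        unit_acc, unit_name = _RT_UNIT[sp.get("rt_unit", "second")]
        mz_b64 = _b64(sp["mz"])
        int_b64 = _b64(sp["intensity"])
        mode_cv = _MODE_CV.get(mode, "") if mode else ""
        parts.append(
            f"""   <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(sp['mz'])}">
    <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>
    {mode_cv}
    <scanList count="1">
     <scan>
      <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{sp['rt']}" unitCvRef="UO" unitAccession="{unit_acc}" unitName="{unit_name}"/>
     </scan>
    </scanList>
    <binaryDataArrayList count="2">
     <binaryDataArray encodedLength="{len(mz_b64)}">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
      <binary>{mz_b64}</binary>
     </binaryDataArray>
     <binaryDataArray encodedLength="{len(int_b64)}">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
      <binary>{int_b64}</binary>
     </binaryDataArray>
    </binaryDataArrayList>
   </spectrum>
"""
        )
    parts.append(_FOOTER)
    path.write_text("".join(parts))
    return path
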