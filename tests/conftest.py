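"""Shared fixtures: tiny synthetic samples, studies and a minimal FCS writer."""

import struct

import numpy as np
import pytest

from cytoqot import CytometrySample, harmonize


def make_sample(rng, *, sample_id="s", subject_id="sub", timepoint="T1",
                means=((0.0, 0.0),), n_cells=200, spread=1.0, n_markers=None):
    """Gaussian-blob sample: one blob per row of `means`."""
    means = np.atleast_2d(np.asarray(means, dtype=float))
    m = means.shape[1] if n_markers is None else n_markers
    if means.shape[1] < m:
        pad = np.zeros((means.shape[0], m - means.shape[1]))
        means = np.hstack([means, pad])
    blocks = [rng.normal(mu, spread, size=(n_cells, m)) for mu in means]
    markers = tuple(f"M{i + 1:02d}" for i in range(m))
    return CytometrySample(sample_id=sample_id, subject_id=subject_id,
                           timepoint=timepoint, matrix=np.vstack(blocks),
                           marker_names=markers)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_blob_sample(rng):
    return make_sample(rng, means=[(0.0, 0.0), (10.0, 10.0)], n_cells=250)


@pytest.fixture
def tiny_study(rng):
    """2 subjects x 2 timepoints, 4 markers; subjects offset in M01/M02."""
    samples = []
    for i, sub in enumerate(["A", "B"]):
        for t in ["T1", "T2"]:
            off = 8.0 * i
            samples.append(make_sample(
                rng, sample_id=f"{sub}_{t}", subject_id=sub, timepoint=t,
                means=[(off, off, 0.0, 0.0)], n_cells=150, n_markers=4))
    return harmonize(samples)


def write_minimal_fcs(path, matrix, names, version=b"FCS3.1"):
    """Write a minimal list-mode FCS file with float32 data (synthetic
    fixture for reader tests; not a full-featured writer)."""
    matrix = np.asarray(matrix, dtype="<f4")
    n_tot, n_par = matrix.shape
    kw = {"$MODE": "L", "$DATATYPE": "F", "$BYTEORD": "1,2,3,4",
          "$PAR": str(n_par), "$TOT": str(n_tot), "$NEXTDATA": "0"}
    for i, name in enumerate(names, start=1):
        kw[f"$P{i}N"] = f"ch{i}"
        kw[f"$P{i}S"] = name
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}R"] = "262144"
        kw[f"$P{i}E"] = "0,0"
    delim = "/"
    text = delim + delim.join(f"{k}{delim}{v}" for k, v in kw.items()) + delim
    text_beg = 58
    text_end = text_beg + len(text) - 1
    data_beg = text_end + 1
    data_end = data_beg + matrix.nbytes - 1
    header = (version + b"    "
              + f"{text_beg:>8d}{text_end:>8d}{data_beg:>8d}{data_end:>8d}"
                f"{0:>8d}{0:>8d}".encode("ascii"))
    assert len(header) == 58
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text.encode("ascii"))
        fh.write(matrix.tobytes())
    return path
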