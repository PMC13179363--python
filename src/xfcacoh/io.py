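"""Readers, writers, accelerometer reduction and analysis configuration.

On-disk formats are deliberately language-neutral and binary-free:

* signals — TSV with one row per channel (first field the channel label)
  plus a JSON sidecar holding the sampling rate and metadata;
* EEG — additionally EDF (European Data Format), read via MNE with
  physical scaling applied;
* patterns — 3-column TSV (channel label, filter weight, pattern value);
* configuration and manifests — JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .exceptions import FormatError, ShapeError
from .patterns import SpatialPattern
from .spectral import CrossSpectra, TimeSeriesSet


# ---------------------------------------------------------------------------
# Delimited signal I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_timeseries(ts: TimeSeriesSet, path) -> None:
    """Write a signal block as TSV (row per channel) + JSON sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        for label, row in zip(ts.labels, ts.data):
            fh.write(label + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    meta = {
        "fs": ts.fs,
        "n_channels": ts.n_channels,
        "n_samples": ts.n_samples,
        "labels": list(ts.labels),
        "epochs": [list(e) for e in ts.epochs] if ts.epochs else None,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_timeseries(path, fs: float | None = None) -> TimeSeriesSet:
    """Read a TSV signal block; fs comes from the sidecar unless given."""
    path = Path(path)
    labels, rows = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: malformed row")
            labels.append(parts[0])
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as err:
                raise FormatError(f"{path}:{lineno}: {err}") from None
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise FormatError(f"{path}: inconsistent channel lengths {sorted(lengths)}")
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    if fs is None:
        fs = meta.get("fs")
        if fs is None:
            raise FormatError(f"{path}: no sampling rate (missing sidecar?)")
    elif "fs" in meta and meta["fs"] != fs:
        raise FormatError(
            f"{path}: sidecar fs {meta['fs']} conflicts with requested fs {fs}"
        )
    if meta.get("labels") and meta["labels"] != labels:
        raise FormatError(f"{path}: sidecar labels disagree with file labels")
    epochs = [tuple(e) for e in meta["epochs"]] if meta.get("epochs") else None
    return TimeSeriesSet(np.asarray(rows), float(fs), labels, epochs)


def read_eeg(path, format: str | None = None, fs: float | None = None) -> TimeSeriesSet:
    """Read multichannel EEG from EDF or delimited text.

    The format is inferred from the extension unless given. EDF headers
    provide labels and sampling rate (physical scaling applied); a
    requested ``fs`` conflicting with the header raises ``FormatError``.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "edf":
        import mne

        try:
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        except Exception as err:
            raise FormatError(f"{path}: unreadable EDF ({err})") from None
        header_fs = float(raw.info["sfreq"])
        if fs is not None and fs != header_fs:
            raise FormatError(
                f"{path}: requested fs {fs} conflicts with header fs {header_fs}"
            )
        return TimeSeriesSet(raw.get_data(), header_fs, list(raw.ch_names))
    if fmt in ("tsv", "csv", "txt"):
        return read_timeseries(path, fs)
    raise FormatError(f"unknown EEG format {fmt!r}")


# ---------------------------------------------------------------------------
# Pattern and cross-spectra I/O
# ---------------------------------------------------------------------------

def write_pattern(pattern: SpatialPattern, path, weights=None) -> None:
    """3-column TSV: channel label, filter weight, pattern value."""
    weights = np.zeros_like(pattern.values) if weights is None else np.asarray(weights)
    with open(path, "w") as fh:
        fh.write("label\tweight\tpattern\n")
        for lab, w, v in zip(pattern.labels, weights, pattern.values):
            fh.write(f"{lab}\t{float(w)!r}\t{float(v)!r}\n")


def read_pattern(path) -> tuple[SpatialPattern, np.ndarray]:
    labels, weights, values = [], [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("label"):
            raise FormatError(f"{path}: missing pattern header")
        for lineno, line in enumerate(fh, 2):
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            labels.append(parts[0])
            weights.append(float(parts[1]))
            values.append(float(parts[2]))
    return SpatialPattern(np.asarray(values), labels), np.asarray(weights)


def write_cross_spectra(cs: CrossSpectra, basepath) -> None:
    """Serialize cross-spectra as JSON metadata + flattened re/im TSV."""
    basepath = Path(basepath)
    meta = {
        "n_segments": cs.n_segments,
        "p_a": cs.caa.shape[1],
        "p_b": cs.cbb.shape[1],
        "n_bins": len(cs.freqs),
    }
    with open(basepath.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    with open(basepath.with_suffix(".tsv"), "w") as fh:
        fh.write("freq_hz\tblock\trow\tcol\tre\tim\n")
        for name, block in (("caa", cs.caa), ("cbb", cs.cbb), ("cab", cs.cab)):
            for k, f in enumerate(cs.freqs):
                mat = block[k]
                for i in range(mat.shape[0]):
                    for j in range(mat.shape[1]):
                        fh.write(
                            f"{float(f)!r}\t{name}\t{i}\t{j}\t"
                            f"{float(mat[i, j].real)!r}\t{float(mat[i, j].imag)!r}\n"
                        )


def read_cross_spectra(basepath) -> CrossSpectra:
    basepath = Path(basepath)
    with open(basepath.with_suffix(".json")) as fh:
        meta = json.load(fh)
    pa, pb, nb = meta["p_a"], meta["p_b"], meta["n_bins"]
    caa = np.zeros((nb, pa, pa), complex)
    cbb = np.zeros((nb, pb, pb), complex)
    cab = np.zeros((nb, pa, pb), complex)
    freqs: dict[float, int] = {}
    with open(basepath.with_suffix(".tsv")) as fh:
        fh.readline()
        for line in fh:
            f_s, name, i, j, re, im = line.split("\t")
            f = float(f_s)
            k = freqs.setdefault(f, len(freqs))
            val = complex(float(re), float(im))
            {"caa": caa, "cbb": cbb, "cab": cab}[name][k, int(i), int(j)] = val
    order = np.argsort(list(freqs))
    fr = np.asarray(sorted(freqs))
    return CrossSpectra(
        freqs=fr,
        caa=caa[order],
        cbb=cbb[order],
        cab=cab[order],
        n_segments=meta["n_segments"],
    )


# ---------------------------------------------------------------------------
# Accelerometer reduction
# ---------------------------------------------------------------------------

def acc_first_pc(acc3d: TimeSeriesSet) -> TimeSeriesSet:
    """First principal component of a 3-axis accelerometer signal.

    The three channels are mean-centered and projected onto the first
    principal axis, retaining a quasi-oscillatory univariate signal
    (unlike the always-positive Euclidean norm). Sign convention: the
    loading with the largest magnitude is positive.
    """
    if acc3d.n_channels != 3:
        raise ShapeError("acc_first_pc expects exactly 3 channels")
    x = acc3d.data - acc3d.data.mean(axis=1, keepdims=True)
    cov = x @ x.T / x.shape[1]
    if np.allclose(cov, 0):
        raise ShapeError("accelerometer signal has zero variance")
    w, v = np.linalg.eigh(cov)
    loading = v[:, -1]
    k = int(np.argmax(np.abs(loading)))
    if loading[k] < 0:
        loading = -loading
    pc = loading @ x
    out = TimeSeriesSet(pc[None, :], acc3d.fs, ["acc_pc1"], acc3d.epochs)
    out.explained_variance_ratio = float(w[-1] / w.sum())  # type: ignore[attr-defined]
    out.loading = loading  # type: ignore[attr-defined]
    return out


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AnalysisConfig:
    """Serializable configuration shared by the workflows and the CLI."""

    segment_len_s: float = 1.0
    overlap_frac: float = 0.5
    taper: str = "hann"
    f_base: float = 3.0
    half_bw_hz: float = 1.0
    ratios: tuple[int, ...] = (2, 3)
    n_restarts: int = 10
    tol: float = 1e-12
    max_iter: int = 200
    gamma: float = 1e-4
    n_perm: int = 1000
    epoch_len_s: float = 1.0
    seed: int = 0
    out_dir: str = "."

    def to_json(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        payload["ratios"] = list(self.ratios)
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "AnalysisConfig":
        try:
            is_file = Path(str(source)).exists()
        except OSError:
            is_file = False
        text = Path(source).read_text() if is_file else str(source)
        payload = json.loads(text)
        payload["ratios"] = tuple(payload.get("ratios", (2, 3)))
        return cls(**payload)
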