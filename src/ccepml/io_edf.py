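"""EDF epoch files and the cohort manifest.

One stimulation test = one EDF file holding the averaged post-stimulus ECoG
epoch (8 or 16 channels, 300 ms at 25 kHz -> 7500 samples per channel, in
microvolts). Clinical metadata — patient identity, surgical phase, recording
quality, and the pre/post speech-dysfunction scores (Luria scale, 0–45,
0 = norm) — travels in a separate manifest CSV, never in EDF headers.

Reading goes through :func:`mne.io.read_raw_edf`; writing uses a minimal
EDF encoder (16-bit, single data record) since no installed library exports
plain EDF.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EcogEpoch",
    "LabelledTest",
    "IngestError",
    "FormatError",
    "ValidationError",
    "CANONICAL_CHANNELS",
    "MANIFEST_COLUMNS",
    "read_epoch_file",
    "write_epoch_file",
    "standardize_channels",
    "read_manifest",
    "load_cohort",
    "make_target",
]

#: channel counts accepted on ingest
ALLOWED_CHANNEL_COUNTS = (8, 16)
#: channel count every epoch is standardized to
CANONICAL_CHANNELS = 16
#: exact manifest header, in order
MANIFEST_COLUMNS = [
    "test_id",
    "file_path",
    "patient_id",
    "phase",
    "quality_ok",
    "pre_score",
    "post_score",
]

SCORE_MIN, SCORE_MAX = 0, 45

# EDF physical range used on export; ±1000 μV over 16 bits gives a
# quantization step of ~0.03 μV, well under recording precision.
_PHYS_MIN, _PHYS_MAX = -1000.0, 1000.0
_DIG_MIN, _DIG_MAX = -32768, 32767


class IngestError(RuntimeError):
    """A file could not be read as an EDF epoch."""


class FormatError(RuntimeError):
    """An EDF file parsed but violates the epoch format contract."""


class ValidationError(ValueError):
    """Manifest contents violate the cohort schema."""


@dataclass
class EcogEpoch:
    """One stimulation test: channels × samples, in microvolts.

    ``present`` marks real channels; after :func:`standardize_channels`
    an 8-channel test carries 8 padded rows flagged absent, which every
    channel-wise statistic must skip.
    """

    test_id: str
    patient_id: str
    phase: str  # "pre" | "post"
    samples: np.ndarray  # (n_channels, n_samples) float64, μV
    sampling_rate: float = 25_000.0
    epoch_ms: float = 300.0
    present: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise FormatError("samples must be a 2-D channels × samples array")
        if not np.isfinite(self.samples).all():
            raise FormatError(f"non-finite sample values in test {self.test_id!r}")
        if self.present is None:
            self.present = np.ones(self.samples.shape[0], dtype=bool)
        else:
            self.present = np.asarray(self.present, dtype=bool)
        expected = round(self.sampling_rate * self.epoch_ms / 1000.0)
        if self.samples.shape[1] != expected:
            raise FormatError(
                f"test {self.test_id!r}: expected {expected} samples per channel "
                f"({self.sampling_rate:g} Hz × {self.epoch_ms:g} ms), "
                f"got {self.samples.shape[1]}"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class LabelledTest:
    """An epoch joined with its binary outcome (1 = speech worsened)."""

    test_id: str
    patient_id: str
    epoch: EcogEpoch
    target: int


def make_target(pre_score: int, post_score: int) -> int:
    """Binary outcome from the 0–45 speech-dysfunction scores.

    1 iff the post-surgery score exceeds the pre-surgery score (function
    worsened); 0 when it improved or remained unchanged.
    """
    for name, s in (("pre_score", pre_score), ("post_score", post_score)):
        if not (SCORE_MIN <= s <= SCORE_MAX):
            raise ValidationError(f"{name}={s} outside [{SCORE_MIN}, {SCORE_MAX}]")
    return int(post_score > pre_score)


# ---------------------------------------------------------------------------
# EDF read / write
# ---------------------------------------------------------------------------

def _channel_labels(n: int) -> list[str]:
    return [f"ECOG{i + 1:02d}" for i in range(n)]


def write_epoch_file(path: str | Path, samples: np.ndarray,
                     sampling_rate: float = 25_000.0) -> None:
    """Write one epoch as a plain EDF file (one data record, 16-bit).

    ``samples`` is (n_channels, n_samples) in microvolts; values are clipped
    to the ±1000 μV physical range.
    """
    samples = np.asarray(samples, dtype=float)
    n_ch, n_samp = samples.shape
    record_dur = n_samp / sampling_rate  # seconds

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValueError(f"EDF field overflow: {text!r} > {width}")
        return b.ljust(width)

    header = b"".join([
        pad("0", 8),                      # version
        pad("X X X X", 80),               # local patient id (anonymous)
        pad("Startdate X X X X", 80),     # local recording id
        pad("01.01.00", 8),               # start date
        pad("00.00.00", 8),               # start time
        pad(str(256 * (1 + n_ch)), 8),    # header byte count
        pad("", 44),                      # reserved
        pad("1", 8),                      # number of data records
        pad(f"{record_dur:.6g}", 8),      # record duration, s
        pad(str(n_ch), 4),                # number of signals
    ])
    labels = _channel_labels(n_ch)
    sig = b"".join([
        b"".join(pad(lab, 16) for lab in labels),
        b"".join(pad("subdural electrode", 80) for _ in labels),
        b"".join(pad("uV", 8) for _ in labels),
        b"".join(pad(f"{_PHYS_MIN:g}", 8) for _ in labels),
        b"".join(pad(f"{_PHYS_MAX:g}", 8) for _ in labels),
        b"".join(pad(str(_DIG_MIN), 8) for _ in labels),
        b"".join(pad(str(_DIG_MAX), 8) for _ in labels),
        b"".join(pad("", 80) for _ in labels),   # prefiltering
        b"".join(pad(str(n_samp), 8) for _ in labels),
        b"".join(pad("", 32) for _ in labels),   # reserved
    ])
    gain = (_DIG_MAX - _DIG_MIN) / (_PHYS_MAX - _PHYS_MIN)
    digital = np.rint(
        (np.clip(samples, _PHYS_MIN, _PHYS_MAX) - _PHYS_MIN) * gain + _DIG_MIN
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        fh.write(digital.tobytes())  # record = all samples ch0, then ch1, ...


def read_epoch_file(path: str | Path, *, test_id: str = "", patient_id: str = "",
                    phase: str = "pre") -> EcogEpoch:
    """Read one EDF epoch file into an :class:`EcogEpoch` (microvolts).

    Identity metadata comes from the manifest via the keyword arguments;
    EDF headers contribute only acquisition parameters.
    """
    import mne

    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001 — rewrap with the offending path
        raise IngestError(f"cannot read EDF file {path}: {exc}") from exc
    data = raw.get_data(units="uV")
    if data.shape[0] not in ALLOWED_CHANNEL_COUNTS:
        raise FormatError(
            f"{path}: {data.shape[0]} channels; expected one of "
            f"{ALLOWED_CHANNEL_COUNTS}"
        )
    return EcogEpoch(
        test_id=test_id or path.stem,
        patient_id=patient_id,
        phase=phase,
        samples=np.asarray(data, dtype=float),
        sampling_rate=float(raw.info["sfreq"]),
        epoch_ms=1000.0 * data.shape[1] / float(raw.info["sfreq"]),
    )


def standardize_channels(epoch: EcogEpoch,
                         canonical: int = CANONICAL_CHANNELS) -> EcogEpoch:
    """Pad to the canonical channel count with absent-channel markers.

    Padded rows are zero-filled but flagged absent so channel-wise maxima,
    means and selection never see them; a 16-channel epoch passes through
    unchanged.
    """
    n = epoch.n_channels
    if n > canonical:
        raise FormatError(f"{n} channels exceeds canonical count {canonical}")
    if n == canonical:
        return epoch
    pad = np.zeros((canonical - n, epoch.n_samples))
    return replace(
        epoch,
        samples=np.vstack([epoch.samples, pad]),
        present=np.concatenate([epoch.present, np.zeros(canonical - n, bool)]),
    )


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def read_manifest(manifest_path: str | Path) -> pd.DataFrame:
    """Parse and validate the cohort manifest CSV."""
    df = pd.read_csv(manifest_path, dtype={"test_id": str, "patient_id": str})
    if list(df.columns) != MANIFEST_COLUMNS:
        raise ValidationError(
            f"manifest header must be exactly {','.join(MANIFEST_COLUMNS)}; "
            f"got {','.join(map(str, df.columns))}"
        )
    if df["test_id"].duplicated().any():
        dupes = df.loc[df["test_id"].duplicated(), "test_id"].tolist()
        raise ValidationError(f"duplicate test_id values: {dupes}")
    bad_phase = set(df["phase"]) - {"pre", "post"}
    if bad_phase:
        raise ValidationError(f"unknown phase values: {sorted(bad_phase)}")
    for col in ("pre_score", "post_score"):
        out = df[(df[col] < SCORE_MIN) | (df[col] > SCORE_MAX)]
        if len(out):
            raise ValidationError(
                f"{col} outside [{SCORE_MIN}, {SCORE_MAX}] for tests "
                f"{out['test_id'].tolist()}"
            )
        per_patient = df.groupby("patient_id")[col].nunique()
        varies = per_patient[per_patient > 1]
        if len(varies):
            raise ValidationError(
                f"{col} differs across tests of patients {varies.index.tolist()}"
            )
    df["quality_ok"] = df["quality_ok"].astype(bool)
    return df


def load_cohort(manifest_path: str | Path, data_dir: str | Path | None = None,
                *, phase: str | None = "pre",
                require_quality: bool = True) -> list[LabelledTest]:
    """Load the analyzable cohort: quality-passing tests of the given phase.

    Mirrors the study restriction to screened pre-resection tests; pass
    ``phase=None`` or ``require_quality=False`` to lift either filter.
    """
    manifest_path = Path(manifest_path)
    data_dir = Path(data_dir) if data_dir is not None else manifest_path.parent
    df = read_manifest(manifest_path)
    if require_quality:
        df = df[df["quality_ok"]]
    if phase is not None:
        df = df[df["phase"] == phase]
    paths = [data_dir / p for p in df["file_path"]]
    missing = [str(p) for p in paths if not p.exists()]
    if missing:
        raise IngestError("missing epoch files: " + ", ".join(missing))
    out = []
    for (_, row), path in zip(df.iterrows(), paths):
        epoch = read_epoch_file(path, test_id=row["test_id"],
                                patient_id=row["patient_id"], phase=row["phase"])
        epoch = standardize_channels(epoch)
        out.append(LabelledTest(
            test_id=row["test_id"],
            patient_id=row["patient_id"],
            epoch=epoch,
            target=make_target(int(row["pre_score"]), int(row["post_score"])),
        ))
    return out
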