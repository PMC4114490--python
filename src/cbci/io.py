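"""Dataset and results serialisation, plus real-data ingest.

Simulated and real sessions follow one on-disk layout:

    dataset/
      manifest.json           parameters, seeds, package version
      trials.tsv              shared trial sequence
      behaviour_<ID>.tsv      per-observer decisions and response times
      epochs.h5               response-locked epochs, one group per observer

Real multi-channel EEG is ingested from EDF/BDF (via mne, if installed)
with events taken from a sidecar TSV (columns sample, kind, trial).
"""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import ContinuousRecording
from .simulate import Population, Session
from .task import read_trials_tsv, write_trials_tsv

EPOCH_CONTAINER_VERSION = 1


def _pkg_version() -> str:
    try:
        return version("cbci")
    except PackageNotFoundError:
        return "unknown"


def write_manifest(path: Path, params: dict) -> None:
    manifest = {"package": "cbci", "version": _pkg_version(), **params}
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path: Path) -> dict:
    return json.loads(Path(path).read_text())


def write_population(outdir, population: Population, manifest_params: dict | None = None) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_trials_tsv(population.trials, outdir / "trials.tsv")
    with h5py.File(outdir / "epochs.h5", "w") as h5:
        h5.attrs["container_version"] = EPOCH_CONTAINER_VERSION
        h5.attrs["locking"] = "response"
        for session in population.sessions:
            session.behaviour.to_csv(
                outdir / f"behaviour_{session.participant_id}.tsv", sep="\t", index=False
            )
            if session.epochs is not None:
                grp = h5.create_group(session.participant_id)
                grp.create_dataset("epochs", data=session.epochs, compression="gzip")
                grp.create_dataset("trial_index", data=session.behaviour["trial"].to_numpy())
    if manifest_params is not None:
        write_manifest(outdir / "manifest.json", manifest_params)
    return outdir


def read_population(datadir) -> Population:
    datadir = Path(datadir)
    trials = read_trials_tsv(datadir / "trials.tsv")
    sessions = []
    epochs_path = datadir / "epochs.h5"
    h5 = h5py.File(epochs_path, "r") if epochs_path.exists() else None
    try:
        for path in sorted(datadir.glob("behaviour_*.tsv")):
            pid = path.stem.removeprefix("behaviour_")
            behaviour = pd.read_csv(path, sep="\t")
            epochs = None
            if h5 is not None and pid in h5:
                epochs = np.asarray(h5[pid]["epochs"])
            sessions.append(Session(pid, behaviour, epochs))
    finally:
        if h5 is not None:
            h5.close()
    if not sessions:
        raise FileNotFoundError(f"no behaviour_*.tsv files in {datadir}")
    return Population(trials, sessions)


def read_events_tsv(path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    missing = {"sample", "kind", "trial"} - set(events.columns)
    if missing:
        raise ValueError(f"events file lacks columns: {sorted(missing)}")
    return events


def load_recording(path, events_tsv=None) -> ContinuousRecording:
    """Read an EDF/BDF recording (requires the optional mne dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError("reading EDF/BDF requires the 'edf' extra (mne)") from exc
    path = Path(path)
    reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    events = read_events_tsv(events_tsv) if events_tsv is not None else None
    kwargs = {} if events is None else {"events": events}
    return ContinuousRecording(
        data=data, rate=float(raw.info["sfreq"]), channel_names=list(raw.ch_names), **kwargs
    )


def write_results(outdir, results) -> Path:
    """Write the analysis report tables as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results.votes.to_csv(outdir / "votes.tsv", sep="\t", index=False)
    results.method_size.to_csv(outdir / "group_error_by_method.tsv", sep="\t", index=False)
    results.fastest.to_csv(outdir / "fastest_responders.tsv", sep="\t", index=False)
    results.best_member_gap.to_csv(outdir / "best_member_gap.tsv", sep="\t", index=False)
    results.weight_medians["by_correctness"].to_csv(outdir / "weight_medians_by_correctness.tsv", sep="\t")
    results.weight_medians["by_dom"].to_csv(outdir / "weight_medians_by_dom.tsv", sep="\t")
    if results.erp_contrast is not None:
        results.erp_contrast.to_csv(outdir / "erp_contrast.tsv", sep="\t", index=False)
    return outdir
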