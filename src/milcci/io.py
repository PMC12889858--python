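"""Dataset container, label tables and spike-train preprocessing.

The on-disk container is HDF5 (``.h5``/``.hdf5``) with groups

* ``/trials/<trial_id>`` -- one 2-D float dataset per trial,
* ``/labels`` -- trial ids plus one string dataset per category,
* ``/categories/<name>`` -- options, budget ``p``, ordinal values,
* ``/truth`` (optional) -- ground-truth component tensors and traces,

with a ``format_version`` root attribute.  An NPZ fallback (``.npz``)
serializes the same content for dependency-light use.  Round trips are
lossless: values bitwise, labels exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    CategorySpec,
    ComponentTensor,
    InvalidLabelError,
    TraceMatrix,
    TrialObservations,
    assign_trace_rows,
)
from .synthetic import GroundTruth

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_labels_csv",
    "read_labels_csv",
    "spikes_to_rates",
    "FORMAT_VERSION",
]

FORMAT_VERSION = "1"


# ---------------------------------------------------------------------------
# container


def _specs_to_json(specs: Sequence[CategorySpec]) -> str:
    return json.dumps(
        [
            {
                "name": s.name,
                "options": [str(o) for o in s.options],
                "p": s.p,
                "ordinal_values": s.ordinal_values,
            }
            for s in specs
        ]
    )


def _specs_from_json(payload: str) -> list[CategorySpec]:
    specs = [
        CategorySpec(
            name=d["name"],
            options=d["options"],
            p=d["p"],
            ordinal_values=d["ordinal_values"],
        )
        for d in json.loads(payload)
    ]
    return assign_trace_rows(specs)


def write_dataset(
    path: str | Path,
    trials: Sequence[TrialObservations],
    specs: Sequence[CategorySpec],
    truth: GroundTruth | None = None,
) -> None:
    """Persist a dataset (and optionally its ground truth) to disk."""
    path = Path(path)
    if path.suffix == ".npz":
        _write_npz(path, trials, specs, truth)
        return
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["categories"] = _specs_to_json(specs)
        grp = f.create_group("trials")
        for trial in trials:
            grp.create_dataset(str(trial.trial_id), data=trial.values)
        lab = f.create_group("labels")
        lab.create_dataset("trial_id", data=np.array([t.trial_id for t in trials]))
        for ci, spec in enumerate(specs):
            lab.create_dataset(
                spec.name,
                data=np.array([str(t.label[ci]) for t in trials], dtype=object),
                dtype=h5py.string_dtype(),
            )
        if truth is not None:
            tg = f.create_group("truth")
            for tensor in truth.tensors:
                tg.create_dataset(f"tensor_{tensor.category.name}", data=tensor.values)
            trg = tg.create_group("traces")
            for trace in truth.traces:
                trg.create_dataset(str(trace.trial_id), data=trace.values)


def _write_npz(path, trials, specs, truth):
    payload = {
        "__meta__": np.array(
            json.dumps(
                {
                    "format_version": FORMAT_VERSION,
                    "trial_ids": [int(t.trial_id) for t in trials],
                    "labels": [[str(o) for o in t.label] for t in trials],
                    "has_truth": truth is not None,
                }
            )
        ),
        "__categories__": np.array(_specs_to_json(specs)),
    }
    for trial in trials:
        payload[f"trial_{trial.trial_id}"] = trial.values
    if truth is not None:
        for tensor in truth.tensors:
            payload[f"truth_tensor_{tensor.category.name}"] = tensor.values
        for trace in truth.traces:
            payload[f"truth_trace_{trace.trial_id}"] = trace.values
    np.savez(path, **payload)


def read_dataset(
    path: str | Path, return_truth: bool = False
):
    """Load a dataset container; optionally also its ground-truth group.

    Validates the schema: every trial appears exactly once in the label
    table, all trials share the channel count, and every label option is
    known to its category (violations name the offending trial).
    """
    path = Path(path)
    if path.suffix == ".npz":
        return _read_npz(path, return_truth)
    import h5py

    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version != FORMAT_VERSION:
            raise ValueError(f"unsupported container format version {version!r}")
        specs = _specs_from_json(f.attrs["categories"])
        trial_ids = [int(i) for i in f["labels/trial_id"][()]]
        if len(set(trial_ids)) != len(trial_ids):
            raise ValueError("label table lists a trial id more than once")
        label_cols = {
            spec.name: [v.decode() if isinstance(v, bytes) else str(v) for v in f[f"labels/{spec.name}"][()]]
            for spec in specs
        }
        container_ids = sorted(int(k) for k in f["trials"].keys())
        if container_ids != sorted(trial_ids):
            raise ValueError("trial ids in container and label table disagree")
        trials = []
        for row, tid in enumerate(trial_ids):
            label = tuple(label_cols[spec.name][row] for spec in specs)
            values = f[f"trials/{tid}"][()]
            trials.append(_validated_trial(tid, values, label, specs, trials))
        truth = None
        if return_truth and "truth" in f:
            tensors = [
                ComponentTensor(category=spec, values=f[f"truth/tensor_{spec.name}"][()])
                for spec in specs
            ]
            traces = [
                TraceMatrix(trial_id=t.trial_id, values=f[f"truth/traces/{t.trial_id}"][()])
                for t in trials
            ]
            truth = GroundTruth(
                tensors=tensors,
                traces=traces,
                labels=[t.label for t in trials],
                specs=specs,
            )
    if return_truth:
        return trials, specs, truth
    return trials, specs


def _validated_trial(tid, values, label, specs, existing) -> TrialObservations:
    for spec, option in zip(specs, label):
        try:
            spec.option_index(option)
        except InvalidLabelError:
            raise InvalidLabelError(
                f"trial {tid}: option {option!r} is not a valid option of "
                f"category {spec.name!r}"
            ) from None
    trial = TrialObservations(trial_id=tid, values=values, label=label)
    if existing and trial.n_channels != existing[0].n_channels:
        raise ValueError(
            f"trial {tid} has {trial.n_channels} channels, expected "
            f"{existing[0].n_channels}"
        )
    return trial


def _read_npz(path, return_truth):
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        if meta["format_version"] != FORMAT_VERSION:
            raise ValueError(
                f"unsupported container format version {meta['format_version']!r}"
            )
        specs = _specs_from_json(str(data["__categories__"]))
        trials = []
        for tid, label in zip(meta["trial_ids"], meta["labels"]):
            trials.append(
                _validated_trial(tid, data[f"trial_{tid}"], tuple(label), specs, trials)
            )
        truth = None
        if return_truth and meta.get("has_truth"):
            tensors = [
                ComponentTensor(category=spec, values=data[f"truth_tensor_{spec.name}"])
                for spec in specs
            ]
            traces = [
                TraceMatrix(trial_id=t.trial_id, values=data[f"truth_trace_{t.trial_id}"])
                for t in trials
            ]
            truth = GroundTruth(
                tensors=tensors, traces=traces, labels=[t.label for t in trials], specs=specs
            )
    if return_truth:
        return trials, specs, truth
    return trials, specs


# ---------------------------------------------------------------------------
# label tables


def write_labels_csv(path: str | Path, trials: Sequence[TrialObservations], specs: Sequence[CategorySpec]) -> None:
    """Write the label table as CSV: trial_id plus one column per category."""
    rows = {
        "trial_id": [t.trial_id for t in trials],
        **{
            spec.name: [t.label[ci] for t in trials]
            for ci, spec in enumerate(specs)
        },
    }
    pd.DataFrame(rows).to_csv(path, index=False)


def read_labels_csv(path: str | Path, specs: Sequence[CategorySpec]) -> dict[int, tuple]:
    """Read a CSV label table into a trial_id -> label mapping."""
    df = pd.read_csv(path, dtype={spec.name: str for spec in specs})
    labels = {}
    for _, row in df.iterrows():
        tid = int(row["trial_id"])
        label = tuple(str(row[spec.name]) for spec in specs)
        for spec, option in zip(specs, label):
            try:
                spec.option_index(option)
            except InvalidLabelError:
                raise InvalidLabelError(
                    f"trial {tid}: option {option!r} is not a valid option of "
                    f"category {spec.name!r}"
                ) from None
        labels[tid] = label
    return labels


# ---------------------------------------------------------------------------
# spike preprocessing


def spikes_to_rates(
    spike_times: Sequence[np.ndarray],
    t_start: float,
    t_end: float,
    bin_width: float = 0.010,
    kernel_sd: float = 0.050,
    min_rate: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate smoothed firing rates and drop inactive neurons.

    Spikes are binned at ``bin_width`` seconds (bin ``t`` covers
    ``[t_start + t*bin_width, t_start + (t+1)*bin_width)``), convolved with
    a unit-sum Gaussian kernel of standard deviation ``kernel_sd`` seconds
    truncated at +-4 sd, and divided by ``bin_width`` to yield Hz.  Spikes
    outside ``[t_start, t_end)`` are ignored.  Neurons with mean rate below
    ``min_rate`` Hz (including spikeless neurons) are dropped.

    Returns ``(rates, kept)`` where ``rates`` is ``n_kept x n_bins`` in Hz
    and ``kept`` holds the original neuron indices retained.
    """
    if bin_width <= 0 or kernel_sd <= 0:
        raise ValueError("bin_width and kernel_sd must be positive")
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    n_bins = int(np.floor((t_end - t_start) / bin_width + 1e-9))
    if n_bins < 1:
        raise ValueError("window shorter than one bin")
    edges = t_start + bin_width * np.arange(n_bins + 1)

    radius = int(np.ceil(4.0 * kernel_sd / bin_width))
    x = np.arange(-radius, radius + 1) * bin_width
    kernel = np.exp(-(x**2) / (2.0 * kernel_sd**2))
    kernel /= kernel.sum()

    rates = np.empty((len(spike_times), n_bins))
    for i, st in enumerate(spike_times):
        st = np.asarray(st, dtype=float)
        st = st[(st >= t_start) & (st < edges[-1])]
        counts, _ = np.histogram(st, bins=edges)
        rates[i] = np.convolve(counts, kernel, mode="same") / bin_width

    kept = np.nonzero(rates.mean(axis=1) >= min_rate)[0]
    return rates[kept], kept
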