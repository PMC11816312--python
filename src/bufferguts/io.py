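"""Delimited-text readers and writers.

All on-disk formats are plain text: comma-separated tables with a header
row, plus ``#``-prefixed key-value metadata lines where a table needs
context (units, TU flag). Every writer has a matching reader and
write-read-write round trips are byte-stable (floats are rendered with a
fixed ``%.10g`` format).
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .calibration import Replicate, SurvivalDataset, Treatment
from .exposure import DoseResponseFit, ExposureEvent, ExposureProfile, Route

__all__ = [
    "read_events",
    "write_events",
    "read_survival_data",
    "write_survival_data",
    "read_profile",
    "write_profile",
    "read_dose_response",
    "write_dose_response",
    "read_config",
    "write_config",
]

_F = "%.10g"


def _fmt(x: float) -> str:
    return _F % float(x)


class MalformedRowError(ValueError):
    """Raised with the 1-based line number of the offending row."""

    def __init__(self, path, line_no, message):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


# ---------------------------------------------------------------------------
# exposure events
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ["treatment", "route", "magnitude", "unit", "t_start_days", "t_end_days"]


def write_events(path, events_by_treatment: dict[str, list[ExposureEvent]]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(EVENT_COLUMNS)
        for label, events in events_by_treatment.items():
            for ev in events:
                w.writerow([label, ev.route.value, _fmt(ev.magnitude), ev.unit,
                            _fmt(ev.t_start), _fmt(ev.t_end)])


def read_events(path) -> dict[str, list[ExposureEvent]]:
    """Read an exposure-event table; returns treatment label -> events.

    A file without the leading ``treatment`` column is read as a single
    unnamed treatment ``""``.
    """
    out: dict[str, list[ExposureEvent]] = {}
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        return out
    header = [h.strip() for h in rows[0]]
    has_treatment = header[0] == "treatment"
    expected = EVENT_COLUMNS if has_treatment else EVENT_COLUMNS[1:]
    if header != expected:
        raise MalformedRowError(path, 1, f"expected header {expected}, got {header}")
    for ln, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        try:
            if has_treatment:
                label, route, mag, unit, t0, t1 = row
            else:
                route, mag, unit, t0, t1 = row
                label = ""
            ev = ExposureEvent(Route(route.strip()), float(mag), float(t0), float(t1),
                               unit.strip())
        except (ValueError, KeyError) as exc:
            raise MalformedRowError(path, ln, str(exc)) from exc
        out.setdefault(label, []).append(ev)
    return out


# ---------------------------------------------------------------------------
# survival datasets
# ---------------------------------------------------------------------------

DATA_COLUMNS = ["study_id", "treatment", "replicate", "time_days", "n_alive", "n_initial"]


def write_survival_data(path, dataset: SurvivalDataset) -> None:
    study = str(dataset.metadata.get("study_id", "study"))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        for key in sorted(k for k in dataset.metadata if k != "study_id"):
            fh.write(f"# {key}={dataset.metadata[key]}\n")
        w.writerow(DATA_COLUMNS)
        for tr in dataset.treatments:
            for ri, rep in enumerate(tr.replicates):
                for t_obs, n in zip(rep.times, rep.n_alive):
                    w.writerow([study, tr.label, ri, _fmt(t_obs), int(n), rep.n0])


def read_survival_data(path, events_by_treatment=None) -> SurvivalDataset:
    """Read a survivor-count table.

    ``events_by_treatment`` (from :func:`read_events`) attaches exposure
    events; treatments absent from the mapping are zero-exposure controls.
    """
    meta: dict = {}
    rows = []
    with open(path, newline="") as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            rows.append((ln, line))
    parsed = list(csv.reader(r[1] for r in rows))
    if not parsed:
        raise MalformedRowError(path, 1, "empty survival data file")
    header = [h.strip() for h in parsed[0]]
    if header != DATA_COLUMNS:
        raise MalformedRowError(path, rows[0][0], f"expected header {DATA_COLUMNS}, got {header}")
    records: dict[tuple[str, str], dict] = {}
    study_id = None
    for (ln, _), row in zip(rows[1:], parsed[1:]):
        if not row or all(not c.strip() for c in row):
            continue
        try:
            study_id, label, rep, t_obs, n, n0 = (c.strip() for c in row)
            key = (label, rep)
            rec = records.setdefault(key, {"t": [], "n": [], "n0": int(n0)})
            rec["t"].append(float(t_obs))
            rec["n"].append(int(n))
            if int(n0) != rec["n0"]:
                raise ValueError("inconsistent n_initial within replicate")
        except ValueError as exc:
            raise MalformedRowError(path, ln, str(exc)) from exc
    meta["study_id"] = study_id
    treatments: dict[str, Treatment] = {}
    for (label, _), rec in records.items():
        order = np.argsort(rec["t"])
        rep = Replicate(np.array(rec["t"])[order], np.array(rec["n"])[order], rec["n0"])
        if label not in treatments:
            events = (events_by_treatment or {}).get(label, [])
            treatments[label] = Treatment(label=label, replicates=[], events=events)
        treatments[label].replicates.append(rep)
    return SurvivalDataset(list(treatments.values()), metadata=meta)


# ---------------------------------------------------------------------------
# profiles, dose-response fits, config
# ---------------------------------------------------------------------------

def write_profile(path, profile: ExposureProfile) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# unit={profile.unit_label}\n")
        fh.write(f"# toxic_units={int(profile.is_toxic_units)}\n")
        fh.write(f"# dense={int(profile.is_dense)}\n")
        w = csv.writer(fh)
        w.writerow(["time_days", "level"])
        if profile.is_dense:
            for t_i, v in zip(profile.dense_t, profile.dense_values):
                w.writerow([_fmt(t_i), _fmt(v)])
        else:
            for b, lvl in zip(profile.breakpoints, profile.levels):
                w.writerow([_fmt(b), _fmt(lvl)])


def read_profile(path) -> ExposureProfile:
    meta = {}
    data_lines = []
    with open(path, newline="") as fh:
        for line in fh:
            if line.startswith("#"):
                k, v = line[1:].strip().split("=", 1)
                meta[k.strip()] = v.strip()
            else:
                data_lines.append(line)
    parsed = list(csv.reader(data_lines))
    t_vals = np.array([float(r[0]) for r in parsed[1:] if r])
    levels = np.array([float(r[1]) for r in parsed[1:] if r])
    dense = bool(int(meta.get("dense", "0")))
    if dense:
        return ExposureProfile(np.array([0.0]), np.array([0.0]),
                               unit_label=meta.get("unit", ""),
                               is_toxic_units=bool(int(meta.get("toxic_units", "0"))),
                               dense_t=t_vals, dense_values=levels)
    return ExposureProfile(t_vals, levels, unit_label=meta.get("unit", ""),
                           is_toxic_units=bool(int(meta.get("toxic_units", "0"))))


def write_dose_response(path, fit: DoseResponseFit) -> None:
    with open(path, "w") as fh:
        fh.write(f"lc50={_fmt(fit.lc50)}\n")
        fh.write(f"slope={_fmt(fit.slope)}\n")
        fh.write(f"timepoint={_fmt(fit.timepoint)}\n")
        fh.write(f"endpoint_label={fit.endpoint_label}\n")
        if fit.fitted_timepoint is not None:
            fh.write(f"fitted_timepoint={_fmt(fit.fitted_timepoint)}\n")


def read_dose_response(path) -> DoseResponseFit:
    kv = read_config(path)
    return DoseResponseFit(
        lc50=float(kv["lc50"]),
        slope=float(kv["slope"]),
        timepoint=float(kv["timepoint"]),
        endpoint_label=kv.get("endpoint_label", "LC50"),
        fitted_timepoint=float(kv["fitted_timepoint"]) if "fitted_timepoint" in kv else None,
    )


def read_config(path) -> dict[str, str]:
    """Flat ``key=value`` text config; blank lines and ``#`` comments ignored."""
    out = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise MalformedRowError(path, ln, f"expected key=value, got {line!r}")
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def write_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        for k in config:
            fh.write(f"{k}={config[k]}\n")


# ---------------------------------------------------------------------------
# calibration result bundles
# ---------------------------------------------------------------------------

def save_result(prefix, result) -> tuple[str, str]:
    """Write a calibration result as ``<prefix>.json`` (summaries and
    diagnostics) plus ``<prefix>_samples.csv`` (posterior sample table)."""
    import json as _json

    prefix = str(prefix)
    json_path, csv_path = prefix + ".json", prefix + "_samples.csv"
    with open(json_path, "w") as fh:
        fh.write(result.to_json() + "\n")
    chains, draws, d = result.samples.shape
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["chain", "draw", *result.param_names])
        for c in range(chains):
            for i in range(draws):
                w.writerow([c, i, *(_fmt(v) for v in result.samples[c, i])])
    return json_path, csv_path


def load_result(prefix):
    """Inverse of :func:`save_result`."""
    import json as _json

    from .calibration import CalibrationResult, MCMCSettings
    from .tktd import ModelVariant

    prefix = str(prefix)
    with open(prefix + ".json") as fh:
        payload = _json.load(fh)
    names = tuple(payload["param_names"])
    rows = []
    with open(prefix + "_samples.csv", newline="") as fh:
        r = csv.reader(fh)
        header = next(r)
        assert header == ["chain", "draw", *names]
        for row in r:
            rows.append([float(v) for v in row])
    arr = np.array(rows)
    n_chains = int(arr[:, 0].max()) + 1
    samples = arr[:, 2:].reshape(n_chains, -1, len(names))
    s = payload["settings"]
    return CalibrationResult(
        model=ModelVariant(payload["model"]),
        param_names=names,
        samples=samples,
        summary=payload["summary"],
        diagnostics=payload["diagnostics"],
        settings=MCMCSettings(s["chains"], s["tune"], s["draws"], s["target_accept"]),
        seed=payload["seed"],
    )
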