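"""CSV/JSON writers and readers for the package's result types."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .coordination import ComplexStateSeries, DistanceSeries, TransitionReport
from .itc import ITCExperiment, ITCFitResult, ITCProtocol
from .landscape import PMFResult
from .solvation import RDFResult
from .synthetic import GroundTruth

__all__ = [
    "write_ground_truth",
    "write_itc_experiment",
    "read_itc_experiment",
    "write_states_csv",
    "write_transition_report",
    "write_rdf_csv",
    "write_pmf_csv",
    "write_fit_report",
    "write_series_csv",
]


def write_ground_truth(gt: GroundTruth, csv_path: str | Path,
                       json_path: str | Path | None = None) -> None:
    df = gt.to_frame()
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        payload = {
            "n_frames": gt.n_frames,
            "complex_state": list(map(str, gt.complex_state)),
            "n5_state": list(map(str, gt.n5_state)),
            "n_bound_waters": [int(x) for x in gt.n_bound_waters],
            "bound_water_ids": [list(map(int, ids)) for ids in gt.bound_water_ids],
        }
        Path(json_path).write_text(json.dumps(payload))


def write_itc_experiment(exp: ITCExperiment, csv_path: str | Path,
                         json_path: str | Path | None = None) -> None:
    """CSV of (injection, volume_uL, heat_ucal) plus a JSON protocol header."""
    df = pd.DataFrame(
        {
            "injection": np.arange(len(exp.heats)),
            "volume_uL": exp.protocol.injection_volumes,
            "heat_ucal": exp.heats,
        }
    )
    if exp.blank_heats is not None:
        df["blank_ucal"] = exp.blank_heats
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        hdr = {
            "T": exp.protocol.T, "V0_mL": exp.protocol.V0,
            "M0_uM": exp.protocol.M0, "X0_uM": exp.protocol.X0,
            "true_params": exp.true_params,
        }
        Path(json_path).write_text(json.dumps(hdr))


def read_itc_experiment(csv_path: str | Path,
                        json_path: str | Path | None = None) -> ITCExperiment:
    df = pd.read_csv(csv_path)
    kwargs = {}
    if json_path is not None and Path(json_path).exists():
        hdr = json.loads(Path(json_path).read_text())
        kwargs = dict(T=hdr["T"], V0=hdr["V0_mL"], M0=hdr["M0_uM"], X0=hdr["X0_uM"])
    protocol = ITCProtocol(
        injection_volumes=tuple(df["volume_uL"].tolist()), **kwargs
    )
    blank = df["blank_ucal"].to_numpy() if "blank_ucal" in df.columns else None
    return ITCExperiment(protocol, df["heat_ucal"].to_numpy(), blank_heats=blank)


def write_states_csv(
    path: str | Path,
    distance: DistanceSeries,
    states: ComplexStateSeries,
) -> None:
    pd.DataFrame(
        {
            "frame": np.arange(len(states)),
            "distance_nm": distance.values,
            "n5_state": states.n5_labels,
            "n_waters": states.water_counts,
            "complex_state": states.labels,
        }
    ).to_csv(path, index=False)


def write_transition_report(report: TransitionReport, counts_csv: str | Path,
                            occupancy_json: str | Path) -> None:
    report.counts.to_csv(counts_csv)
    payload = {
        "occupancy": report.occupancy,
        "off_path": [
            {"frame": f, "from": a, "to": b} for f, a, b in report.off_path
        ],
    }
    Path(occupancy_json).write_text(json.dumps(payload))


def write_rdf_csv(rdfres: RDFResult, path: str | Path) -> None:
    pd.DataFrame({"r_nm": rdfres.r, "g": rdfres.g, "n": rdfres.n}).to_csv(
        path, index=False
    )


def write_pmf_csv(pmf: PMFResult, path: str | Path) -> None:
    pd.DataFrame(
        {"r_nm": pmf.r, "F_kcal_mol": pmf.F, "count": pmf.counts}
    ).to_csv(path, index=False)


def write_fit_report(fit: ITCFitResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(fit)))


def write_series_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)
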