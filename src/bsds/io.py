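"""Readers, writers and the on-disk model container.

Text formats throughout: time series as TSV (T rows x D columns, header =
channel names), events as BIDS-dialect TSV (onset, duration, trial_type in
seconds), decoded sequences as single-column TSV, metrics as tidy TSV.
Fitted models persist as one HDF5 file of flat float64 arrays plus a JSON
manifest carrying dimensions, names, TR, seeds and the ELBO trace.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .designs import BlockDesign, make_block_design
from .inference import (
    FitResult,
    LatentTrajectoryPosterior,
    QTheta,
    StatePosterior,
    posterior_state_parameters,
)
from .model import ModelError, TimeSeriesDataset

__all__ = [
    "RunConfig",
    "read_timeseries",
    "write_timeseries",
    "read_events",
    "write_events",
    "save_fit",
    "load_fit",
    "write_sequences",
    "read_sequence",
    "write_metrics",
    "write_matrix",
]


@dataclass
class RunConfig:
    """Validated pipeline configuration; persisted into every manifest."""

    out_dir: str = "."
    K_max: int = 10
    P_max: int | None = None
    R: int = 1
    tol: float = 1e-6
    max_iter: int = 500
    n_restarts: int = 3
    seed: int = 0
    prune_threshold: float | None = None
    sticky_kappa: float = 10.0
    onset_window_s: float = 5.0
    tr: float = 1.0

    def __post_init__(self):
        if self.K_max < 1:
            raise ModelError("K_max must be >= 1")
        if self.R != 1:
            raise ModelError("only AR order R=1 is supported by inference")
        if self.tol <= 0 or self.max_iter < 1 or self.n_restarts < 1:
            raise ModelError("tol, max_iter and n_restarts must be positive")
        if self.tr <= 0 or self.onset_window_s <= 0:
            raise ModelError("tr and onset_window_s must be positive")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, header=0)
    except pd.errors.ParserError as exc:
        raise ModelError(f"{path}: ragged or malformed table ({exc})") from exc
    if df.columns.str.match(r"^(Unnamed|\d+\.?\d*$)").all():
        raise ModelError(f"{path}: missing header row")
    return df


def read_timeseries(
    paths: str | Path | list[str | Path], tr: float, subject_ids: list[str] | None = None
) -> TimeSeriesDataset:
    """Read one TSV/CSV matrix per subject into a dataset.

    Strict parsing: non-numeric cells and NaN/inf are rejected with the
    offending row and column named.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    subjects: dict[str, np.ndarray] = {}
    names: tuple[str, ...] | None = None
    for i, p in enumerate(paths):
        df = _read_table(p)
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce")
            nonnum = df[col].index[bad.isna() & df[col].notna()]
            if len(nonnum):
                raise ModelError(
                    f"{p}: non-numeric cell at row {int(nonnum[0])}, column {col!r}"
                )
        arr = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            t, d = map(int, np.argwhere(~np.isfinite(arr))[0])
            raise ModelError(
                f"{p}: NaN/inf at row {t}, column {df.columns[d]!r}"
            )
        if names is None:
            names = tuple(df.columns)
        elif tuple(df.columns) != names:
            raise ModelError(f"{p}: channel names differ from the first file")
        sid = subject_ids[i] if subject_ids else Path(p).stem
        subjects[sid] = arr
    return TimeSeriesDataset(subjects=subjects, tr=tr, channel_names=names or ())


def write_timeseries(data: TimeSeriesDataset, out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for sid, y in data.subjects.items():
        p = out / f"{sid}_timeseries.tsv"
        pd.DataFrame(y, columns=list(data.channel_names)).to_csv(
            p, sep="\t", index=False, float_format="%.10g"
        )
        paths.append(p)
    return paths


def read_events(path: str | Path, tr: float, n_frames: int | None = None,
                rest_label: str = "rest") -> BlockDesign:
    """Read a BIDS-dialect events table (onset, duration, trial_type)."""
    df = _read_table(path)
    need = {"onset", "duration", "trial_type"}
    if not need.issubset(df.columns):
        raise ModelError(f"{path}: events need columns {sorted(need)}")
    intervals = [
        (float(r.onset), float(r.duration), str(r.trial_type))
        for r in df.itertuples()
    ]
    return make_block_design(intervals, tr=tr, n_frames=n_frames, rest_label=rest_label)


def write_events(design: BlockDesign, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [(o, d, c) for o, d, c in design.intervals],
        columns=["onset", "duration", "trial_type"],
    ).to_csv(path, sep="\t", index=False)
    return path


def write_sequences(seqs: dict[str, np.ndarray], out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for sid, labels in seqs.items():
        p = out / f"{sid}_states.tsv"
        pd.DataFrame({"state": np.asarray(labels, dtype=int)}).to_csv(
            p, sep="\t", index=False
        )
        paths.append(p)
    return paths


def read_sequence(path: str | Path) -> np.ndarray:
    df = _read_table(path)
    return df.iloc[:, 0].to_numpy(dtype=int)


def write_metrics(rows: list[dict], path: str | Path) -> Path:
    """Tidy TSV: one row per (subject, condition, state, metric, value)."""
    path = Path(path)
    pd.DataFrame(rows, columns=["subject", "condition", "state", "metric", "value"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
    return path


def write_matrix(M: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(np.asarray(M)).to_csv(path, sep="\t", index=False, header=False,
                                       float_format="%.10g")
    return path


# ---------------------------------------------------------------------------
# Model container: HDF5 arrays + JSON manifest


def save_fit(fit: FitResult, path: str | Path) -> Path:
    """Persist a fit as `<path>.h5` + `<path>.json`."""
    import h5py

    path = Path(path)
    h5path = path.with_suffix(".h5")
    q = fit.qtheta
    with h5py.File(h5path, "w") as f:
        g = f.create_group("qtheta")
        for name in ("alpha_pi", "alpha_A", "m_w", "S_w", "a_psi", "b_psi",
                     "m_g", "S_g", "a_sig", "b_sig", "b_nu"):
            g.create_dataset(name, data=np.asarray(getattr(q, name), dtype="<f8"))
        g.attrs["a_nu"] = float(q.a_nu)
        f.create_dataset("elbo_trace", data=np.asarray(fit.elbo_trace, dtype="<f8"))
        zg = f.create_group("state_posteriors")
        xg = f.create_group("latent_posteriors")
        for sid, zp in fit.state_posteriors.items():
            sg = zg.create_group(sid)
            sg.create_dataset("gamma", data=zp.gamma.astype("<f8"))
            sg.create_dataset("xi", data=zp.xi.astype("<f8"))
            sg.attrs["logZ"] = float(zp.logZ)
            xp = fit.latent_posteriors[sid]
            sx = xg.create_group(sid)
            sx.create_dataset("mean", data=xp.mean.astype("<f8"))
            sx.create_dataset("cov", data=xp.cov.astype("<f8"))
            sx.create_dataset("lag_cov", data=xp.lag_cov.astype("<f8"))
            sx.attrs["logdet_prec"] = float(xp.logdet_prec)
    manifest = {
        "format": "bsds-fit",
        "version": 1,
        "K_effective": fit.K_effective,
        "effective_P": [int(v) for v in fit.effective_P],
        "config": _jsonable(fit.config),
        "elbo_final": float(fit.elbo_trace[-1]) if len(fit.elbo_trace) else None,
        "arrays": h5path.name,
    }
    jpath = path.with_suffix(".json")
    jpath.write_text(json.dumps(manifest, indent=2))
    return h5path


def load_fit(path: str | Path) -> FitResult:
    import h5py

    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    with h5py.File(path.with_suffix(".h5"), "r") as f:
        g = f["qtheta"]
        q = QTheta(
            alpha_pi=g["alpha_pi"][()], alpha_A=g["alpha_A"][()],
            m_w=g["m_w"][()], S_w=g["S_w"][()],
            a_psi=g["a_psi"][()], b_psi=g["b_psi"][()],
            m_g=g["m_g"][()], S_g=g["S_g"][()],
            a_sig=g["a_sig"][()], b_sig=g["b_sig"][()],
            a_nu=float(g.attrs["a_nu"]), b_nu=g["b_nu"][()],
        )
        elbo = f["elbo_trace"][()]
        zposts, xposts = {}, {}
        for sid in f["state_posteriors"]:
            sg = f["state_posteriors"][sid]
            sx = f["latent_posteriors"][sid]
            zposts[sid] = StatePosterior(
                gamma=sg["gamma"][()], xi=sg["xi"][()],
                loglik_contrib=np.zeros_like(sg["gamma"][()]),
                logZ=float(sg.attrs["logZ"]),
            )
            xposts[sid] = LatentTrajectoryPosterior(
                mean=sx["mean"][()], cov=sx["cov"][()],
                lag_cov=sx["lag_cov"][()],
                logdet_prec=float(sx.attrs["logdet_prec"]),
            )
    config = manifest.get("config", {})
    if "channel_names" in config:
        config["channel_names"] = tuple(config["channel_names"])
    return FitResult(
        params=posterior_state_parameters(q),
        qtheta=q,
        state_posteriors=zposts,
        latent_posteriors=xposts,
        elbo_trace=np.asarray(elbo),
        K_effective=int(manifest["K_effective"]),
        effective_P=np.asarray(manifest["effective_P"], dtype=int),
        config=config,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_manifest(out_dir: str | Path, name: str, payload: dict) -> Path:
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {"tool": "bsds", "version": __version__, **_jsonable(payload)}
    p = out / f"{name}_manifest.json"
    p.write_text(json.dumps(payload, indent=2))
    return p
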