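"""File formats: frame sequences, provenance-stamped CSV tables, manifests.

Frame sequences are stored in a plain-text container (``.eitseq``): a header
of ``# key: value`` lines (grid shape, sampling rate, session label, subject
id, frame count) followed by one whitespace-separated row block per frame.
Values are written with 17 significant digits, so a write→read round trip is
bit-exact for double precision.

Every CSV table written by the pipeline carries a provenance comment line
(config hash and seed) so outputs can be traced to the exact run settings.

The cohort manifest is a compact per-patient CSV of phantom recipes from
which session movies are rebuilt deterministically; the accompanying YAML
holds the cohort-level parameters.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import RunConfig
from .signals import FrameSequence
from .synthetic import (
    Cohort,
    CohortSpec,
    GIDistribution,
    PatientInput,
    SessionParams,
    T1Effects,
    T2Effects,
    VTModel,
)

_FMT = "%.17g"


# ---------------------------------------------------------------------------
# frame container


def write_frames(seq: FrameSequence, path: str | Path) -> None:
    path = Path(path)
    rows, cols = seq.grid_shape
    with path.open("w") as fh:
        fh.write("# eitseq v1\n")
        fh.write(f"# subject_id: {seq.subject_id}\n")
        fh.write(f"# session_label: {seq.session_label}\n")
        fh.write(f"# sampling_rate: {seq.sampling_rate!r}\n")
        fh.write(f"# grid_shape: {rows} {cols}\n")
        fh.write(f"# n_frames: {seq.n_frames}\n")
        for frame in seq.frames:
            for row in frame:
                fh.write(" ".join(_FMT % v for v in row))
                fh.write("\n")
            fh.write("\n")


def read_frames(path: str | Path) -> FrameSequence:
    path = Path(path)
    meta: dict[str, str] = {}
    values: list[float] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            if line:
                values.extend(float(tok) for tok in line.split())
    for required in ("grid_shape", "sampling_rate", "n_frames"):
        if required not in meta:
            raise ValueError(f"frame container {path} is missing the {required} field")
    rows, cols = (int(tok) for tok in meta["grid_shape"].split())
    n_frames = int(meta["n_frames"])
    expected = n_frames * rows * cols
    if len(values) != expected:
        raise ValueError(
            f"frame container {path} is truncated or corrupt: expected "
            f"{expected} values for {n_frames} frames of {rows}×{cols}, "
            f"got {len(values)}"
        )
    frames = np.array(values, dtype=float).reshape(n_frames, rows, cols)
    return FrameSequence(
        frames=frames,
        sampling_rate=float(meta["sampling_rate"]),
        session_label=meta.get("session_label", "t0"),
        subject_id=meta.get("subject_id", ""),
    )


# ---------------------------------------------------------------------------
# provenance-stamped tables


def write_table(df: pd.DataFrame, path: str | Path, cfg: RunConfig) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# provenance: config_sha256={cfg.sha256()} seed={cfg.seed}\n")
        # %.17g round-trips doubles exactly through text
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    # round_trip parsing keeps %.17g-written doubles bit-exact
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def read_provenance(path: str | Path) -> dict:
    first = Path(path).open().readline()
    if not first.startswith("# provenance:"):
        return {}
    fields = dict(tok.split("=", 1) for tok in first.split()[2:])
    return fields


# ---------------------------------------------------------------------------
# cohort manifest


def cohort_to_manifest(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for p in cohort.patients:
        row = {
            "subject_id": p.subject_id,
            "latent_deteriorated": p.latent_deteriorated,
            "vt_t0": p.vt_t0,
            "vt_t2": p.vt_t2,
            "hotspot_seed": p.hotspot_seed,
        }
        for label in ("t0", "t1", "t2"):
            row[f"gi_score_{label}"] = p.gi_scores[label]
            s = p.sessions[label]
            row[f"gi_movie_raw_{label}"] = s.gi_movie_raw
            row[f"amp_scale_{label}"] = s.amp_scale
            row[f"delay_fraction_{label}"] = s.delay_fraction
            row[f"rr_{label}"] = s.rr
            row[f"eeli_shift_tiv_{label}"] = s.eeli_shift_tiv
            row[f"movie_seed_{label}"] = s.movie_seed
        rows.append(row)
    return pd.DataFrame(rows)


def manifest_to_cohort(df: pd.DataFrame, spec: CohortSpec,
                       theoretical_auc: float) -> Cohort:
    patients = []
    for _, row in df.iterrows():
        sessions = {}
        gi_scores = {}
        for label in ("t0", "t1", "t2"):
            gi_scores[label] = float(row[f"gi_score_{label}"])
            sessions[label] = SessionParams(
                gi_movie_raw=float(row[f"gi_movie_raw_{label}"]),
                amp_scale=float(row[f"amp_scale_{label}"]),
                delay_fraction=float(row[f"delay_fraction_{label}"]),
                rr=float(row[f"rr_{label}"]),
                eeli_shift_tiv=float(row[f"eeli_shift_tiv_{label}"]),
                movie_seed=int(row[f"movie_seed_{label}"]),
            )
        patients.append(
            PatientInput(
                subject_id=str(row["subject_id"]),
                latent_deteriorated=bool(row["latent_deteriorated"]),
                vt_t0=float(row["vt_t0"]),
                vt_t2=float(row["vt_t2"]),
                gi_scores=gi_scores,
                sessions=sessions,
                hotspot_seed=int(row["hotspot_seed"]),
            )
        )
    return Cohort(patients=patients, theoretical_auc=theoretical_auc, spec=spec)


def write_cohort(cohort: Cohort, out_dir: str | Path, cfg: RunConfig) -> None:
    """Write manifest.csv, cohort.yaml and truth.csv into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(cohort_to_manifest(cohort), out / "manifest.csv", cfg)
    spec_dict = dataclasses.asdict(cohort.spec)
    spec_dict["grid_shape"] = list(cohort.spec.grid_shape)
    (out / "cohort.yaml").write_text(
        yaml.safe_dump(
            {"spec": spec_dict, "theoretical_auc": cohort.theoretical_auc},
            sort_keys=True,
        )
    )
    truth = pd.DataFrame(
        [
            {
                "subject_id": p.subject_id,
                "latent_deteriorated": p.latent_deteriorated,
                "vt_t0": p.vt_t0,
                "vt_t2": p.vt_t2,
                "gi_score_t0": p.gi_scores["t0"],
                "gi_score_t1": p.gi_scores["t1"],
                "gi_score_t2": p.gi_scores["t2"],
            }
            for p in cohort.patients
        ]
    )
    write_table(truth, out / "truth.csv", cfg)


def read_cohort(in_dir: str | Path) -> Cohort:
    in_dir = Path(in_dir)
    blob = yaml.safe_load((in_dir / "cohort.yaml").read_text())
    sd = blob["spec"]
    spec = CohortSpec(
        n_patients=sd["n_patients"],
        deterioration_fraction=sd["deterioration_fraction"],
        gi_model=GIDistribution(**sd["gi_model"]),
        t1_effects=T1Effects(**sd["t1_effects"]),
        t2_effects=T2Effects(**sd["t2_effects"]),
        vt_model=VTModel(**sd["vt_model"]),
        grid_shape=tuple(sd["grid_shape"]),
        sampling_rate=sd["sampling_rate"],
        duration=sd["duration"],
        inspiration_fraction=sd["inspiration_fraction"],
        baseline_rr_mean=sd["baseline_rr_mean"],
        baseline_rr_sd=sd["baseline_rr_sd"],
        delay_spread_fraction=sd["delay_spread_fraction"],
        amp_scale_log_sd=sd["amp_scale_log_sd"],
        hotspot_fraction=sd["hotspot_fraction"],
        noise_sd_fraction=sd["noise_sd_fraction"],
        cardiac_fraction=sd["cardiac_fraction"],
        cardiac_rate=sd["cardiac_rate"],
        gi_session_jitter_sd=sd["gi_session_jitter_sd"],
        seed=sd["seed"],
    )
    manifest = read_table(in_dir / "manifest.csv")
    return manifest_to_cohort(manifest, spec, float(blob["theoretical_auc"]))
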