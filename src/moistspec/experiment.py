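"""Full study orchestration: simulate, preprocess, split, fit the two EPO
corrections, calibrate PLSR models by rdCV and validate within and across
domains.

Per instrument and soil parameter the study produces 7 within-domain rows
(three raw calibration sets: field_moist, lab_sieved, lab_fine; four
EPO-corrected: sieved_EPO_s, field_EPO_s, fine_EPO_f, field_EPO_f) and 4
cross-domain rows (lab-calibrated models predicting the field validation
spectra, raw and EPO-corrected).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import hashlib
import json

import numpy as np
import pandas as pd

from . import epo as epo_mod
from .datatypes import SpectraSet
from .metrics import evaluate
from .pls import fit_pls, predict, rdcv
from .preprocess import PreprocessParams, preprocess_pipeline
from .sampling import SplitPlan, make_split, select_epo_subset
from .synthetic import SyntheticConfig, generate_dataset

PARAMETERS = ("clay", "soc", "ntot")

WITHIN_LABELS = (
    "field_moist",
    "lab_sieved",
    "lab_fine",
    "sieved_EPO_s",
    "field_EPO_s",
    "fine_EPO_f",
    "field_EPO_f",
)

#: (calibration set, validation set, report label) for cross-domain rows.
CROSS_PAIRINGS = (
    ("lab_sieved", "field_moist", "lab_sieved-field_moist"),
    ("lab_fine", "field_moist", "lab_fine-field_moist"),
    ("sieved_EPO_s", "field_EPO_s", "sieved_EPO_s-field_EPO_s"),
    ("fine_EPO_f", "field_EPO_f", "fine_EPO_f-field_EPO_f"),
)

_EPO_TAG = {
    "field_moist": "none",
    "lab_sieved": "none",
    "lab_fine": "none",
    "sieved_EPO_s": "epo_s",
    "field_EPO_s": "epo_s",
    "fine_EPO_f": "epo_f",
    "field_EPO_f": "epo_f",
    "lab_sieved-field_moist": "none",
    "lab_fine-field_moist": "none",
    "sieved_EPO_s-field_EPO_s": "epo_s",
    "fine_EPO_f-field_EPO_f": "epo_f",
}


@dataclass
class StudyConfig:
    """All knobs of one study run; nested configs carry their own defaults."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    ratio: float = 0.70
    epo_n: int = 10
    g_max: int = 10
    k_scores: int = 5
    lv_max: int = 15
    repetitions: int = 100
    outer_folds: int = 4
    inner_folds: int = 10
    parameters: tuple = PARAMETERS
    instruments: tuple = ("full_range", "short_range")
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.parameters or not self.instruments:
            raise ValueError("need at least one parameter and one instrument")
        unknown = set(self.parameters) - set(PARAMETERS)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")

    def to_yaml(self, path) -> None:
        import yaml

        from .synthetic import AbsorptionBand

        payload = {**self.__dict__}
        synth = {**self.synthetic.__dict__}
        synth["bands"] = [b.__dict__ for b in synth["bands"]]
        payload["synthetic"] = synth
        payload["parameters"] = list(self.parameters)
        payload["instruments"] = list(self.instruments)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        from .synthetic import AbsorptionBand, SyntheticConfig

        with open(path) as fh:
            payload = yaml.safe_load(fh)
        synth = payload.pop("synthetic")
        synth["bands"] = [AbsorptionBand(**b) for b in synth["bands"]]
        payload["synthetic"] = SyntheticConfig(**synth)
        payload["parameters"] = tuple(payload.get("parameters", PARAMETERS))
        payload["instruments"] = tuple(
            payload.get("instruments", ("full_range", "short_range"))
        )
        return cls(**payload)


@dataclass
class StudyReport:
    """Flat table of validation rows plus per-stage provenance."""

    frame: pd.DataFrame
    provenance: list = field(default_factory=list)

    #: display column order follows the study's result-table convention
    _CSV_COLUMNS = (
        "instrument", "parameter", "dataset_label", "domain", "epo",
        "final_lv", "g", "rmsep", "r2", "ccc", "rpiq", "bias", "n",
    )

    def to_csv(self, path) -> None:
        out = self.frame.loc[:, list(self._CSV_COLUMNS)].copy()
        for col in ("rmsep", "r2", "ccc", "rpiq", "bias"):
            out[col] = out[col].round(2)
        out.to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.frame.to_json(path, orient="records", indent=2)

    def write_provenance(self, path) -> None:
        """Provenance as JSON lines, one record per pipeline stage."""
        with open(path, "w") as fh:
            for record in self.provenance:
                fh.write(json.dumps(record, default=str) + "\n")


def stage_seed(root_seed: int, name: str) -> int:
    """Deterministic per-stage seed derived from the root seed by a named
    hash, so stages can be rerun in isolation."""
    digest = hashlib.blake2s(f"{root_seed}/{name}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def build_datasets(
    processed: dict[str, SpectraSet],
    split: SplitPlan,
    epo_s: epo_mod.EPOModel,
    epo_f: epo_mod.EPOModel,
) -> dict[str, tuple[SpectraSet, SpectraSet]]:
    """Assemble the 7 calibration/validation dataset pairs.

    ``processed`` maps treatment -> processed per-sample SpectraSet; the
    shared split is applied to every variant so all datasets hold the same
    samples.
    """
    missing = {"field_moist", "lab_sieved", "lab_fine"} - set(processed)
    if missing:
        raise ValueError(f"missing processed treatments: {sorted(missing)}")
    variants = {
        "field_moist": processed["field_moist"],
        "lab_sieved": processed["lab_sieved"],
        "lab_fine": processed["lab_fine"],
        "sieved_EPO_s": epo_mod.apply_epo(processed["lab_sieved"], epo_s),
        "field_EPO_s": epo_mod.apply_epo(processed["field_moist"], epo_s),
        "fine_EPO_f": epo_mod.apply_epo(processed["lab_fine"], epo_f),
        "field_EPO_f": epo_mod.apply_epo(processed["field_moist"], epo_f),
    }
    return {
        label: (
            spectra.reorder_by_ids(split.calibration_ids),
            spectra.reorder_by_ids(split.validation_ids),
        )
        for label, spectra in variants.items()
    }


def _chem_vector(chemistry: pd.DataFrame, ids, parameter: str) -> np.ndarray:
    lookup = chemistry.set_index("sample_id")[parameter]
    return lookup.loc[list(ids)].to_numpy(dtype=float)


def run_within_domain(
    datasets: dict[str, tuple[SpectraSet, SpectraSet]],
    chemistry: pd.DataFrame,
    config: StudyConfig,
    instrument: str,
    g_by_label: dict[str, int],
) -> tuple[list[dict], dict]:
    """rdCV-calibrate and validate each of the 7 datasets for each soil
    parameter.  Also returns the refitted full-calibration models keyed by
    (label, parameter) for cross-domain reuse."""
    rows: list[dict] = []
    models: dict[tuple[str, str], object] = {}
    for label in WITHIN_LABELS:
        cal, val = datasets[label]
        for parameter in config.parameters:
            y_cal = _chem_vector(chemistry, cal.ids, parameter)
            y_val = _chem_vector(chemistry, val.ids, parameter)
            seed = stage_seed(config.seed, f"rdcv/{instrument}/{label}/{parameter}")
            result = rdcv(
                cal.values,
                y_cal,
                lv_max=config.lv_max,
                outer_folds=config.outer_folds,
                inner_folds=config.inner_folds,
                repetitions=config.repetitions,
                seed=seed,
            )
            model = fit_pls(cal.values, y_cal, result.final_lv)
            models[(label, parameter)] = model
            m = evaluate(y_val, predict(model, val.values))
            rows.append(
                {
                    "instrument": instrument,
                    "parameter": parameter,
                    "dataset_label": label,
                    "domain": "within",
                    "epo": _EPO_TAG[label],
                    "final_lv": result.final_lv,
                    "g": g_by_label.get(label),
                    "outer_rmse_mean": result.outer_rmse_mean,
                    "outer_r2_mean": result.outer_r2_mean,
                    **m.as_dict(),
                }
            )
    return rows, models


def run_cross_domain(
    datasets: dict[str, tuple[SpectraSet, SpectraSet]],
    chemistry: pd.DataFrame,
    config: StudyConfig,
    instrument: str,
    models: dict,
    g_by_label: dict[str, int],
) -> list[dict]:
    """Apply the lab-calibrated models (with their lab-selected LV counts)
    to the field validation spectra: the four cross-domain pairings."""
    rows: list[dict] = []
    for cal_label, val_label, report_label in CROSS_PAIRINGS:
        _, val = datasets[val_label]
        for parameter in config.parameters:
            model = models[(cal_label, parameter)]
            y_val = _chem_vector(chemistry, val.ids, parameter)
            m = evaluate(y_val, predict(model, val.values))
            rows.append(
                {
                    "instrument": instrument,
                    "parameter": parameter,
                    "dataset_label": report_label,
                    "domain": "cross",
                    "epo": _EPO_TAG[report_label],
                    "final_lv": model.n_lv,
                    "g": g_by_label.get(cal_label),
                    "outer_rmse_mean": np.nan,
                    "outer_r2_mean": np.nan,
                    **m.as_dict(),
                }
            )
    return rows


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the complete design for every configured instrument.

    Stages: generate -> preprocess (per treatment) -> Kennard-Stone split
    on lab_sieved -> EPO subset -> fit both EPO corrections with Wilk's
    lambda factor selection -> build the 7 dataset pairs -> within-domain
    rdCV + validation -> the 4 cross-domain validations.
    """
    all_rows: list[dict] = []
    provenance: list = []
    for instrument in config.instruments:
        synth = SyntheticConfig(
            **{
                **config.synthetic.__dict__,
                "seed": stage_seed(config.seed, f"simulate/{instrument}"),
            }
        )
        raw, chemistry = generate_dataset(synth, instrument)
        provenance.append({"stage": "simulate", "instrument": instrument,
                           "n_samples": synth.n_samples, "seed": synth.seed})

        params = PreprocessParams.for_instrument(instrument)
        processed: dict[str, SpectraSet] = {}
        for treatment in ("field_moist", "lab_sieved", "lab_fine"):
            spectra, log = preprocess_pipeline(raw.select(treatment=treatment), params)
            processed[treatment] = spectra
            provenance.append({"stage": "preprocess", "instrument": instrument,
                               "treatment": treatment, "log": log})

        split = make_split(processed["lab_sieved"], config.ratio)
        split.epo_ids = select_epo_subset(chemistry, split.calibration_ids, config.epo_n)
        provenance.append({"stage": "split", "instrument": instrument,
                           "n_cal": len(split.calibration_ids),
                           "n_val": len(split.validation_ids),
                           "epo_ids": split.epo_ids})

        epo_s = epo_mod.select_factors(
            processed["field_moist"], processed["lab_sieved"], split.epo_ids,
            g_max=config.g_max, k_scores=config.k_scores,
            pairing="moist_minus_sieved",
        )
        epo_f = epo_mod.select_factors(
            processed["field_moist"], processed["lab_fine"], split.epo_ids,
            g_max=config.g_max, k_scores=config.k_scores,
            pairing="moist_minus_fine",
        )
        provenance.append({"stage": "epo", "instrument": instrument,
                           "g_sieved": epo_s.g, "g_fine": epo_f.g,
                           "lambda_sieved": epo_s.lambda_trace,
                           "lambda_fine": epo_f.lambda_trace})
        g_by_label = {
            "sieved_EPO_s": epo_s.g, "field_EPO_s": epo_s.g,
            "fine_EPO_f": epo_f.g, "field_EPO_f": epo_f.g,
        }

        datasets = build_datasets(processed, split, epo_s, epo_f)
        within_rows, models = run_within_domain(
            datasets, chemistry, config, instrument, g_by_label
        )
        cross_rows = run_cross_domain(
            datasets, chemistry, config, instrument, models, g_by_label
        )
        all_rows.extend(within_rows)
        all_rows.extend(cross_rows)
    return StudyReport(frame=pd.DataFrame(all_rows), provenance=provenance)
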