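"""Table and configuration file formats.

All tables are UTF-8, tab-separated with a header row; missing values are
written as ``NA`` (used only for assays that do not exist under the cross's
rearrangement architecture).  Provenance and statistics reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .genome import ConfigurationError, TranslocationKind, TranslocationSpec, make_homokaryon
from .genotyping import ASSAYS
from .simulate import CrossDataset, SimulationConfig
from .viability import DriveElement, DriveModelParams, MaturationModelParams

NA = "NA"

PROGENY_COLUMNS = ["isolate_id", "ascus_id", "self_fertile", "mating_types", *ASSAYS]
ASCUS_COLUMNS = ["ascus_id", "spore_count", "black", "white", "class_label"]


def write_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)


def write_progeny_table(progeny: pd.DataFrame, path) -> None:
    write_table(progeny, path)


def read_progeny_table(path) -> pd.DataFrame:
    frame = read_table(path)
    missing = [c for c in PROGENY_COLUMNS if c not in frame.columns and c != "ascus_id"]
    if missing:
        raise ConfigurationError(f"progeny table {path} lacks columns: {missing}")
    bad_rows = []
    for assay in ASSAYS:
        ok = frame[assay].isna() | frame[assay].astype("string").isin(["0", "1", "0.0", "1.0"])
        bad_rows.extend(frame.index[~ok].tolist())
    if bad_rows:
        raise ConfigurationError(
            f"progeny table {path}: assay values outside {{0,1,NA}} in rows {sorted(set(bad_rows))}"
        )
    return frame


def write_ascus_table(asci: pd.DataFrame, path) -> None:
    write_table(asci, path)


def read_ascus_table(path) -> pd.DataFrame:
    frame = read_table(path)
    missing = [c for c in ASCUS_COLUMNS if c not in frame.columns]
    if missing:
        raise ConfigurationError(f"ascus table {path} lacks columns: {missing}")
    bad = frame[frame["black"] + frame["white"] != frame["spore_count"]]
    if len(bad):
        raise ConfigurationError(f"ascus table {path}: black+white != spore_count in rows {bad.index.tolist()}")
    return frame


def write_marker_matrix(markers: pd.DataFrame, path) -> None:
    write_table(markers, path)


def read_marker_matrix(path) -> pd.DataFrame:
    return read_table(path)


def write_dataset(dataset: CrossDataset, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "progeny": out / "progeny.tsv",
        "asci": out / "asci.tsv",
        "markers": out / "markers.tsv",
        "provenance": out / "provenance.json",
    }
    write_progeny_table(dataset.progeny, paths["progeny"])
    write_ascus_table(dataset.asci, paths["asci"])
    write_marker_matrix(dataset.markers, paths["markers"])
    paths["provenance"].write_text(json.dumps(dataset.provenance, indent=2, sort_keys=True) + "\n")
    return paths


def spec_from_mapping(section: dict) -> TranslocationSpec:
    if "kind" not in section:
        raise ConfigurationError("translocation: missing required key 'kind'")
    xover = {int(k): float(v) for k, v in (section.get("interstitial_xover_prob") or {}).items()}
    junctions = section.get("junctions")
    return TranslocationSpec(
        kind=TranslocationKind(section["kind"]),
        donor_chrom=int(section.get("donor_chrom", 1)),
        recipient_chrom=int(section.get("recipient_chrom", 2)),
        junctions=frozenset(junctions) if junctions is not None else None,
        interstitial_xover_prob=xover,
        name=str(section.get("name", "")),
    )


def _parent_from_mapping(section: dict, default_label: str) -> "ParentGenotype":
    return make_homokaryon(
        label=str(section.get("label", default_label)),
        mating_type=str(section["mating_type"]),
        translocation=bool(section.get("translocation", False)),
        eight_spore=bool(section.get("eight_spore", False)),
    )


def load_config(path, *, seed: int | None = None, n_asci: int | None = None) -> SimulationConfig:
    """Parse a YAML cross configuration into a :class:`SimulationConfig`.

    Schema (top-level keys)::

        translocation: {kind, donor_chrom, recipient_chrom, junctions?, interstitial_xover_prob?}
        parents: {first: {label, mating_type, translocation?, eight_spore?}, second: {...}}
        species: tetrasperma | crassa
        replacement: {r_base?, r_eight_spore?, override?}
        models:
          maturation: {enabled, viable_threshold?, failure_prob?, per_spore?}
          drive: {enabled, kill_prob?, elements: [{locus, chromosome, parent_of_origin}]}
          germling_t_loss?: float
        pcr: {primer_failure_prob?}
        n_asci: int
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} is not a mapping")
    if "translocation" not in raw:
        raise ConfigurationError("config: missing required section 'translocation'")
    spec = spec_from_mapping(raw["translocation"])
    parents_cfg = raw.get("parents") or {}
    if "first" not in parents_cfg or "second" not in parents_cfg:
        raise ConfigurationError("config: section 'parents' needs 'first' and 'second'")
    parents = (
        _parent_from_mapping(parents_cfg["first"], "parent1"),
        _parent_from_mapping(parents_cfg["second"], "parent2"),
    )
    models = raw.get("models") or {}
    maturation = None
    m_cfg = models.get("maturation") or {}
    if m_cfg.get("enabled"):
        maturation = MaturationModelParams(
            viable_threshold=int(m_cfg.get("viable_threshold", 4)),
            failure_prob=float(m_cfg.get("failure_prob", 1.0)),
            per_spore=bool(m_cfg.get("per_spore", False)),
        )
    drive = None
    d_cfg = models.get("drive") or {}
    if d_cfg.get("enabled"):
        drive = DriveModelParams(
            elements=tuple(
                DriveElement(str(e["locus"]), int(e["chromosome"]), str(e["parent_of_origin"]))
                for e in d_cfg.get("elements", [])
            ),
            kill_prob=float(d_cfg.get("kill_prob", 1.0)),
        )
    replacement = raw.get("replacement") or {}
    pcr = raw.get("pcr") or {}
    return SimulationConfig(
        spec=spec,
        parents=parents,
        n_asci=int(n_asci if n_asci is not None else raw.get("n_asci", 1000)),
        species=str(raw.get("species", "tetrasperma")),
        r_base=float(replacement.get("r_base", 0.08)),
        r_eight_spore=float(replacement.get("r_eight_spore", 0.5)),
        replacement_prob=(float(replacement["override"]) if "override" in replacement else None),
        maturation=maturation,
        drive=drive,
        germling_t_loss=float(models.get("germling_t_loss", 0.0)),
        primer_failure_prob=float(pcr.get("primer_failure_prob", 0.01)),
        mat_sds_prob=float(raw.get("mat_sds_prob", 0.0)),
        seed=seed,
    )
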