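"""Study data model, CSV readers/writers and stratum construction.

A study is four plain CSV tables:

* beta matrix — first column ``sample_id``, remaining columns are CpG probe
  ids; values are methylation beta proportions in [0, 1], missing allowed;
* sample sheet — ``sample_id``, ``species``, ``tissue``, ``age`` (years),
  optional explicit ``stratum_id``;
* traits — keyed by ``stratum_id`` or ``species``; ``max_lifespan`` (years),
  optional ``gestation``, ``adult_weight``, ``median_lifespan``;
* annotation — ``probe_id``, ``chromatin_state``, ``prc2_bound``.

Strata default to species x tissue (mammal mode); in dog mode the breed is
carried in the species column or as an explicit ``stratum_id``.  Probe and
sample orderings are lexicographic throughout so downstream floating-point
reductions are reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import AgeInterval, StratumView, relative_ages, scale_values
from .errors import DegenerateStratumError, ValidationError

__all__ = [
    "StudyBundle",
    "ProbeSet",
    "AgeInterval",
    "StratumView",
    "load_study",
    "select_state_cpgs",
    "build_strata",
    "dog_max_lifespan",
    "write_outputs",
    "stats_to_frame",
]

logger = logging.getLogger(__name__)

DOG_LIFESPAN_FACTOR = 1.33  # max lifespan approx 1.33 x median, by convention

_PRC2_MAP = {
    "+": "+", "yes": "+", "y": "+", "1": "+", "true": "+",
    "-": "-", "no": "-", "n": "-", "0": "-", "false": "-",
    "−": "-",  # unicode minus
}


def normalize_prc2(value) -> str:
    key = str(value).strip().lower()
    try:
        return _PRC2_MAP[key]
    except KeyError:
        raise ValidationError(f"unrecognized PRC2 flag {value!r}") from None


@dataclass(frozen=True)
class ProbeSet:
    """A named CpG set: one chromatin state restricted by PRC2 binding."""

    state: str
    prc2: str
    probes: tuple[str, ...]

    def __post_init__(self):
        if len(self.probes) == 0:
            raise ValidationError(
                f"no CpGs for state {self.state!r} with PRC2 {self.prc2!r}"
            )

    @property
    def label(self) -> str:
        return f"{self.state}{self.prc2}"

    def __len__(self) -> int:
        return len(self.probes)


@dataclass
class StudyBundle:
    """Joined, validated study tables.

    ``betas`` is samples x probes (index sample_id, columns probe ids);
    ``samples`` carries one row per sample with a ``stratum_id`` column;
    ``traits`` is indexed by its key (stratum id or species name);
    ``annotation`` is indexed by probe id.
    """

    betas: pd.DataFrame
    samples: pd.DataFrame
    traits: pd.DataFrame
    annotation: pd.DataFrame

    def validate(self) -> None:
        problems: list[str] = []
        if self.betas.index.has_duplicates:
            dup = self.betas.index[self.betas.index.duplicated()].unique()
            problems.append(f"duplicate sample ids in beta matrix: {list(dup)}")
        if self.betas.columns.has_duplicates:
            dup = self.betas.columns[self.betas.columns.duplicated()].unique()
            problems.append(f"duplicate probe ids in beta matrix: {list(dup)}")
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples.loc[
                self.samples["sample_id"].duplicated(), "sample_id"
            ]
            problems.append(f"duplicate sample ids in sample sheet: {list(dup)}")

        vals = self.betas.to_numpy(dtype=float)
        bad = np.argwhere((vals < 0) | (vals > 1))
        for i, j in bad[:20]:
            problems.append(
                "beta value outside [0, 1] at "
                f"(sample {self.betas.index[i]!r}, probe {self.betas.columns[j]!r}): "
                f"{vals[i, j]}"
            )

        sheet_ids = set(self.samples["sample_id"])
        missing = [s for s in self.betas.index if s not in sheet_ids]
        if missing:
            problems.append(f"beta-matrix samples missing from sample sheet: {missing}")

        for stratum, sub in self.samples.groupby("stratum_id"):
            species = sub["species"].iloc[0]
            if stratum not in self.traits.index and species not in self.traits.index:
                problems.append(
                    f"stratum {stratum!r} (species {species!r}) has no trait record"
                )
            else:
                try:
                    self.lifespan_for(stratum)
                except (KeyError, ValueError) as exc:
                    problems.append(str(exc))
        if problems:
            raise ValidationError(problems)

    def _trait_row(self, stratum_id: str) -> pd.Series:
        if stratum_id in self.traits.index:
            return self.traits.loc[stratum_id]
        species = self.samples.loc[
            self.samples["stratum_id"] == stratum_id, "species"
        ]
        if len(species) and species.iloc[0] in self.traits.index:
            return self.traits.loc[species.iloc[0]]
        raise KeyError(f"no trait record for stratum {stratum_id!r}")

    def lifespan_for(self, stratum_id: str) -> float:
        """Maximum lifespan for a stratum.

        Falls back to the dog convention (1.33 x median lifespan) when the
        trait row carries a median but no maximum.
        """
        row = self._trait_row(stratum_id)
        L = row.get("max_lifespan", np.nan)
        if pd.notna(L):
            if L <= 0:
                raise ValueError(
                    f"non-positive max_lifespan for stratum {stratum_id!r}: {L}"
                )
            return float(L)
        med = row.get("median_lifespan", np.nan)
        if pd.notna(med):
            return dog_max_lifespan(float(med))
        raise ValueError(f"stratum {stratum_id!r} has no usable lifespan trait")

    def gestation_for(self, stratum_id: str) -> float:
        row = self._trait_row(stratum_id)
        gt = row.get("gestation", np.nan)
        return float(gt) if pd.notna(gt) else 0.0


def dog_max_lifespan(median_lifespan_years: float) -> float:
    """Breed maximum lifespan from median lifespan: 1.33 x median."""
    if median_lifespan_years <= 0:
        raise ValueError("median lifespan must be positive")
    return DOG_LIFESPAN_FACTOR * median_lifespan_years


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{name} table is missing column(s): {missing}")


def load_study(beta_path, sample_path, traits_path, annotation_path) -> StudyBundle:
    """Read the four study CSVs, join and validate them."""
    betas = pd.read_csv(beta_path)
    if betas.columns[0] != "sample_id":
        raise ValidationError(
            "beta matrix must have 'sample_id' as its first column, "
            f"found {betas.columns[0]!r}"
        )
    betas = betas.set_index("sample_id")
    betas = betas.reindex(sorted(betas.columns), axis=1).sort_index()

    samples = pd.read_csv(sample_path)
    _require_columns(samples, ["sample_id", "species", "tissue", "age"], "sample")
    if "stratum_id" not in samples.columns or samples["stratum_id"].isna().all():
        samples["stratum_id"] = (
            samples["species"].astype(str) + "__" + samples["tissue"].astype(str)
        )
    samples = samples.sort_values("sample_id").reset_index(drop=True)

    traits = pd.read_csv(traits_path)
    key = "stratum_id" if "stratum_id" in traits.columns else "species"
    if key not in traits.columns:
        raise ValidationError(
            "traits table needs a 'species' or 'stratum_id' key column"
        )
    if "max_lifespan" not in traits.columns and "median_lifespan" not in traits.columns:
        raise ValidationError(
            "traits table needs 'max_lifespan' or 'median_lifespan'"
        )
    traits = traits.set_index(key)

    annotation = pd.read_csv(annotation_path)
    _require_columns(annotation, ["probe_id", "chromatin_state", "prc2_bound"],
                     "annotation")
    annotation["prc2_bound"] = annotation["prc2_bound"].map(normalize_prc2)
    if annotation["probe_id"].duplicated().any():
        dup = annotation.loc[annotation["probe_id"].duplicated(), "probe_id"]
        raise ValidationError(f"duplicate probe ids in annotation: {list(dup)}")
    annotation = annotation.set_index("probe_id").sort_index()

    bundle = StudyBundle(betas=betas, samples=samples, traits=traits,
                         annotation=annotation)
    bundle.validate()
    return bundle


def select_state_cpgs(bundle: StudyBundle, state: str, prc2_flag: str) -> ProbeSet:
    """CpGs in one chromatin state with the given PRC2 binding flag."""
    prc2 = normalize_prc2(prc2_flag)
    ann = bundle.annotation
    mask = (ann["chromatin_state"] == state) & (ann["prc2_bound"] == prc2)
    probes = tuple(sorted(ann.index[mask]))
    if not probes:
        raise ValidationError(
            f"no CpGs annotated to state {state!r} with PRC2 {prc2!r}"
        )
    return ProbeSet(state=state, prc2=prc2, probes=probes)


def build_strata(
    bundle: StudyBundle,
    probeset: ProbeSet,
    interval: AgeInterval | None = None,
    min_n: int = 3,
    use_gestation: bool = True,
    max_missing: float = 0.5,
) -> list[StratumView]:
    """One :class:`StratumView` per stratum with >= ``min_n`` usable samples.

    Per sample, mean methylation is the mean over non-missing probes of the
    set; samples missing more than ``max_missing`` of the probes are dropped
    (logged).  Samples are then restricted to the half-open relative-age
    ``interval``; strata falling below ``min_n`` are omitted (logged), never
    an error.
    """
    if interval is None:
        interval = AgeInterval(0.0, 1.0)
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    probes = [p for p in probeset.probes if p in bundle.betas.columns]
    if not probes:
        raise ValidationError("none of the probe set's CpGs are in the beta matrix")

    views: list[StratumView] = []
    for stratum_id, sub in bundle.samples.groupby("stratum_id", sort=True):
        sub = sub.sort_values("sample_id")
        ids = [s for s in sub["sample_id"] if s in bundle.betas.index]
        if not ids:
            logger.info("stratum %s: no samples in beta matrix; omitted", stratum_id)
            continue
        block = bundle.betas.loc[ids, probes].to_numpy(dtype=float)
        frac_missing = np.isnan(block).mean(axis=1)
        keep = frac_missing <= max_missing
        if not keep.all():
            dropped = [s for s, k in zip(ids, keep) if not k]
            logger.info("stratum %s: dropped %d sample(s) with >%.0f%% missing "
                        "betas: %s", stratum_id, len(dropped),
                        100 * max_missing, dropped)
        ids = [s for s, k in zip(ids, keep) if k]
        block = block[keep]
        with np.errstate(invalid="ignore"):
            methyl = np.nanmean(block, axis=1)

        ages = sub.set_index("sample_id").loc[ids, "age"].to_numpy(dtype=float)
        L = bundle.lifespan_for(stratum_id)
        gt = bundle.gestation_for(stratum_id) if use_gestation else 0.0
        rel = relative_ages(ages, L, gt)
        inside = interval.contains(rel)
        if inside.sum() < min_n:
            logger.info("stratum %s: %d sample(s) in %s < min_n=%d; omitted",
                        stratum_id, int(inside.sum()), interval, min_n)
            continue
        ages, rel, methyl = ages[inside], rel[inside], methyl[inside]
        ids = [s for s, k in zip(ids, inside) if k]
        try:
            scaled = scale_values(methyl)
        except DegenerateStratumError:
            scaled = np.full(methyl.shape, np.nan)
        species = sub["species"].iloc[0]
        tissue = sub["tissue"].iloc[0]
        views.append(StratumView(
            stratum_id=str(stratum_id), ages=ages, rel_ages=rel, methyl=methyl,
            scaled=scaled, L=L, interval=interval, species=str(species),
            tissue=str(tissue), gestation=gt, sample_ids=ids,
        ))
    return views


_STATS_COLUMNS = [
    "stratum_id", "species", "tissue", "n", "interval_lower", "interval_upper",
    "cor_methyl_age", "sd_R", "sd_A", "sd_M", "arocm", "intercept",
    "r_squared", "resid_sd", "L", "gestation",
    "p", "adj_cor", "adj_arocm", "log_adj_cor", "log_adj_arocm", "log_L",
]


def stats_to_frame(stats_list) -> pd.DataFrame:
    """Serialize StratumStats / AdjustedStats records to a tidy table."""
    rows = []
    for s in stats_list:
        row = {
            "stratum_id": s.stratum_id, "species": s.species, "tissue": s.tissue,
            "n": s.n, "interval_lower": s.interval.lower,
            "interval_upper": s.interval.upper,
            "cor_methyl_age": s.cor_methyl_age, "sd_R": s.sd_R, "sd_A": s.sd_A,
            "sd_M": s.sd_M, "arocm": s.arocm, "intercept": s.intercept,
            "r_squared": s.r_squared, "resid_sd": s.resid_sd, "L": s.L,
            "gestation": s.gestation,
        }
        for extra in ("p", "adj_cor", "adj_arocm", "log_adj_cor",
                      "log_adj_arocm", "log_L"):
            if hasattr(s, extra):
                row[extra] = getattr(s, extra)
        rows.append(row)
    frame = pd.DataFrame(rows)
    cols = [c for c in _STATS_COLUMNS if c in frame.columns]
    return frame.reindex(columns=cols) if len(frame) else pd.DataFrame(
        columns=_STATS_COLUMNS[:16])


def write_outputs(tables: Mapping[str, pd.DataFrame], report: Mapping,
                  out_dir) -> dict[str, Path]:
    """Write result tables as CSV plus a structured JSON report.

    Returns a manifest mapping logical names to the files written.  Floats
    go through pandas' default shortest round-trip repr, so read(write(x))
    reproduces x exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    for name, frame in tables.items():
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        manifest[name] = path
    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    manifest["report"] = report_path
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, AgeInterval):
        return [obj.lower, obj.upper]
    if isinstance(obj, Path):
        return str(obj)
    return str(obj)
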