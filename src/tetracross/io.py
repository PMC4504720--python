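"""Table readers/writers and run configuration.

CSV is the canonical interchange format (hand-scored microscopy data
arrives as spreadsheets); TSV is accepted via delimiter sniffing or the
explicit ``delimiter`` argument. All readers validate and report bad
rows by tetrad/cell id rather than silently coercing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tetracross.chiasma import ChiasmaSample
from tetracross.errors import ConfigError, DataError
from tetracross.simulate import SimConfig, Tetrad


class TetradTable(list):
    """A list of Tetrad with a record of rejected input rows."""

    def __init__(self, tetrads=(), rejected=None):
        super().__init__(tetrads)
        self.rejected: list[str] = list(rejected or [])


def _read_delimited(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    if delimiter is None:
        # sniff: prefer tab when the header has tabs and no commas
        head = path.open("r", encoding="utf-8").readline()
        delimiter = "\t" if ("\t" in head and "," not in head) else ","
    return pd.read_csv(path, sep=delimiter)


def read_tetrad_table(path: str | Path, delimiter: str | None = None) -> TetradTable:
    """Read a tetrad grain table into validated Tetrad objects.

    Schema: tetrad_id, grain (1-4), then one 0/1 presence column per
    fluorophore. Tetrads with != 4 grains, duplicate grain numbers or
    non-binary calls are rejected and listed (by tetrad_id) in the
    returned table's ``rejected`` attribute.
    """
    df = _read_delimited(path, delimiter)
    required = {"tetrad_id", "grain"}
    if not required <= set(df.columns):
        raise DataError(
            f"malformed header: need columns {sorted(required)} plus fluorophore columns, "
            f"got {list(df.columns)}"
        )
    marker_cols = [c for c in df.columns if c not in ("tetrad_id", "grain")]
    if not marker_cols:
        raise DataError("malformed header: no fluorophore columns")
    out = TetradTable()
    for tid, grp in df.groupby("tetrad_id", sort=True):
        if len(grp) != 4 or set(grp["grain"]) != {1, 2, 3, 4}:
            out.rejected.append(f"tetrad {tid}: expected grains 1-4, got {sorted(grp['grain'])}")
            continue
        vals = grp.sort_values("grain")[marker_cols].to_numpy()
        if not np.isin(vals, (0, 1)).all():
            out.rejected.append(f"tetrad {tid}: non-binary presence call")
            continue
        grains = tuple(tuple(int(v) for v in row) for row in vals)
        out.append(Tetrad(grains=grains, meta={"tetrad_id": tid}))
    return out


def write_tetrad_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_chiasma_table(path: str | Path, delimiter: str | None = None) -> dict[str, ChiasmaSample]:
    """Read a chiasma CSV (cell_id, chiasmata[, univalents][, genotype])
    into one ChiasmaSample per genotype."""
    df = _read_delimited(path, delimiter)
    if "chiasmata" not in df.columns:
        raise DataError("chiasma table needs a 'chiasmata' column")
    if "genotype" not in df.columns:
        df["genotype"] = ""
    out = {}
    for gt, grp in df.groupby("genotype", sort=True):
        univ = grp["univalents"].to_numpy() if "univalents" in grp.columns else None
        out[str(gt)] = ChiasmaSample(
            counts=grp["chiasmata"].to_numpy(), univalents=univ, genotype=str(gt)
        )
    return out


def write_chiasma_table(sample: ChiasmaSample, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "cell_id": np.arange(len(sample)),
            "chiasmata": sample.counts,
            "univalents": sample.univalents
            if sample.univalents is not None
            else np.zeros(len(sample), dtype=int),
            "genotype": sample.genotype,
        }
    )
    df.to_csv(path, index=False)


def read_intensity_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    df = _read_delimited(path, delimiter)
    required = {"cell_id", "region", "roi_mean", "bead_mean"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"intensity table missing columns: {sorted(missing)}")
    return df


@dataclass
class RunConfig:
    """Pipeline configuration: simulation parameters plus analysis flags.

    Every stochastic run records its seed; outputs embed a provenance
    block (package version, config hash, seed) and are byte-identical
    under identical config + seed.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    outdir: str = "results"
    coc_definition: str = "tetrad"
    gof_mode: str = "pooled"
    intensity_true_reduction: float = 0.67
    intensity_noise: float = 0.1
    intensity_n_cells: int = 23
    chiasma_range: tuple[int, int] = (6, 8)

    def provenance(self) -> dict:
        from tetracross import __version__

        # hash the scientific configuration only; the output location
        # must not change result bytes
        cfg = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        payload = json.dumps(cfg, sort_keys=True).encode()
        return {
            "package": "tetracross",
            "version": __version__,
            "seed": self.sim.seed,
            "config_sha1": hashlib.sha1(payload).hexdigest(),
        }

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["marker_positions_cM"] = list(self.sim.marker_positions_cM)
        d["sim"]["bivalent_lengths_cM"] = list(self.sim.bivalent_lengths_cM)
        d["chiasma_range"] = list(self.chiasma_range)
        return d


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration mirroring RunConfig/SimConfig fields."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("run config must be a YAML mapping")
    sim_raw = raw.pop("sim", {})
    try:
        sim = SimConfig(**sim_raw)
        cfg = RunConfig(sim=sim, **raw)
    except TypeError as exc:
        raise ConfigError(f"unknown configuration field: {exc}") from exc
    if "chiasma_range" in raw or cfg.chiasma_range:
        cfg.chiasma_range = tuple(cfg.chiasma_range)  # type: ignore[assignment]
    return cfg


def save_run_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
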