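"""File formats and reports: FASTA in, dot-bracket lists, TSV/CSV/JSON out.

Every report embeds the package version and a hash of the run configuration
in a leading comment line, so outputs are traceable to their inputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bhg import BasinHoppingGraph
from .kinetics import PopulationSeries
from .landscape import LocalMinimum
from .structures import Sequence, Structure, parse_structure, write_structure

__all__ = [
    "RunConfig",
    "read_fasta",
    "read_structures",
    "write_structures",
    "write_lm_table",
    "write_bhg_tsv",
    "read_bhg_tsv",
    "write_trajectory_csv",
    "write_comparison_tsv",
    "write_path_report",
    "write_equilibrium_json",
]


@dataclass
class RunConfig:
    """Validated knobs of a pipeline run; serialized alongside outputs."""

    sequence_file: str | None = None
    params_file: str | None = None
    ceiling: float = 10.0
    n_samples: int = 1000
    seed: int = 1
    width: int = 16
    rounds: int = 3
    k_lowest: int = 50
    max_states: int = 5000
    report_threshold: float = 0.07
    t_min: float = 1e-2
    t_max: float = 1e18
    per_decade: int = 60

    def __post_init__(self) -> None:
        if self.ceiling <= 0:
            raise ValueError("ceiling must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.width < 1 or self.rounds < 0 or self.max_states < 1:
            raise ValueError("invalid search parameters")
        if not 0 <= self.report_threshold <= 1:
            raise ValueError("report threshold must be a probability")
        if not 0 < self.t_min < self.t_max:
            raise ValueError("invalid time grid bounds")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _header(config: RunConfig | None) -> str:
    h = config.digest() if config is not None else "none"
    return f"# rnabhg {__version__} config_hash={h}\n"


def read_fasta(path) -> list[Sequence]:
    """Read RNA sequences; DNA input (T) is U-normalized with a warning."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        if "T" in residues:
            warnings.warn(
                f"sequence {rec.id}: DNA alphabet, normalizing T -> U"
            )
            residues = residues.replace("T", "U")
        out.append(Sequence(residues, rec.id))
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def read_structures(path, n: int | None = None) -> list[Structure]:
    """One extended dot-bracket structure per line; '#' comments and an
    optional trailing energy column are ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        out.append(parse_structure(line.split()[0], n))
    return out


def write_structures(structures, n: int, path, config: RunConfig | None = None):
    with open(path, "w") as fh:
        fh.write(_header(config))
        for s in structures:
            fh.write(write_structure(s, n) + "\n")


def write_lm_table(
    lms: list[LocalMinimum], n: int, path, config: RunConfig | None = None
) -> None:
    """barriers-style table: index, dot-bracket, energy, pk class, count."""
    with open(path, "w") as fh:
        fh.write(_header(config))
        fh.write("index\tstructure\tenergy\tpk_class\tcount\n")
        for k, lm in enumerate(lms):
            fh.write(
                f"{k}\t{write_structure(lm.structure, n)}\t"
                f"{lm.energy:.2f}\t{lm.pk_class}\t{lm.count}\n"
            )


def write_bhg_tsv(
    bhg: BasinHoppingGraph, path, config: RunConfig | None = None
) -> None:
    from .structures import classify_pk

    with open(path, "w") as fh:
        fh.write(_header(config))
        fh.write("lm_i\tlm_j\tsaddle\twitness_pk\n")
        for a, b, data in sorted(bhg.graph.edges(data=True)):
            w = data.get("witness")
            classes: set[str] = set()
            if w is not None:
                for s in w.structures:
                    c = classify_pk(s)
                    if c != "N":
                        classes.update(c)
            label = "".join(sorted(classes)) or "N"
            fh.write(f"{a}\t{b}\t{data['saddle']:.2f}\t{label}\n")


def read_bhg_tsv(path) -> list[tuple[int, int, float, str]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "lm_i")):
            continue
        a, b, s, label = line.split("\t")
        out.append((int(a), int(b), float(s), label))
    return out


def write_trajectory_csv(
    series: PopulationSeries,
    n: int,
    path,
    config: RunConfig | None = None,
    threshold: float = 0.0,
) -> None:
    """Time column (arbitrary time units, r0^-1) plus one column per state
    whose population ever exceeds the reporting threshold."""
    keep = [
        k
        for k in range(series.populations.shape[1])
        if series.populations[:, k].max() >= threshold
    ]
    cols = {"time": series.times}
    for k in keep:
        cols[write_structure(series.states[k].structure, n)] = series.populations[:, k]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, index=False)


def write_comparison_tsv(df: pd.DataFrame, path, config: RunConfig | None = None):
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=False)


def write_path_report(
    bhg: BasinHoppingGraph,
    nodes: list[int],
    score,
    path,
    config: RunConfig | None = None,
) -> None:
    """Ordered list of minima with energies, edge saddles and per-step
    activation energies; text plus an embedded CSV-like table."""
    n = len(bhg.seq)
    with open(path, "w") as fh:
        fh.write(_header(config))
        fh.write(
            f"# peak={score.peak:.2f} activation={score.activation:.2f}"
            + (f" loglik={score.loglik:.2f}" if score.loglik is not None else "")
            + "\n"
        )
        fh.write("step\tstructure\tenergy\tsaddle_to_next\tactivation\n")
        for k, node in enumerate(nodes):
            lm = bhg.lms[node]
            if k < len(nodes) - 1:
                s = bhg.graph.edges[node, nodes[k + 1]]["saddle"]
                act = s - lm.energy
                fh.write(
                    f"{k}\t{write_structure(lm.structure, n)}\t"
                    f"{lm.energy:.2f}\t{s:.2f}\t{act:.2f}\n"
                )
            else:
                fh.write(
                    f"{k}\t{write_structure(lm.structure, n)}\t"
                    f"{lm.energy:.2f}\t\t\n"
                )


def write_equilibrium_json(
    model, eq_time: float, n: int, path, config: RunConfig | None = None
) -> None:
    from .structures import write_structure as ws

    pi = model.equilibrium()
    data = {
        "version": __version__,
        "config_hash": config.digest() if config else "none",
        "equilibration_time": eq_time if eq_time != float("inf") else "inf",
        "equilibrium": {
            ws(lm.structure, n): float(pi[k])
            for k, lm in enumerate(model.states)
        },
    }
    Path(path).write_text(json.dumps(data, indent=2) + "\n")
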