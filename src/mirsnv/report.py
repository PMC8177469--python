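"""Aggregation of per-variant gain/loss calls into per-gene cohort reports.

Multiple SNVs in one gene are pooled: the gene row carries the union of
miRNA ids gained/lost across its variants.  Genes with both a gain and a
loss are flagged ``mixed`` and excluded from the gain-only / loss-only
lists (they are reported but not analysed further).  A packaged reference
table (a published MTLE cohort's per-gene gain/loss summary) ships with
the package for end-to-end verification of the aggregation logic.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .types import ConsequenceCall, GainLossRecord, StructureDelta, WindowSkip


@dataclass
class GainLossTable:
    """Per-gene gained/lost miRNA sets plus cohort totals."""

    rows: list[dict] = field(default_factory=list)  # gene, gained, lost, annotation

    @property
    def totals(self) -> dict[str, int]:
        # rows transcribed from a printed table may carry explicit per-row
        # counts (n_gained/n_lost) that override the id-list lengths
        n_sites_gained = sum(r.get("n_gained", len(r["gained"])) for r in self.rows)
        n_sites_lost = sum(r.get("n_lost", len(r["lost"])) for r in self.rows)
        genes_gain = [r for r in self.rows if r["gained"]]
        genes_loss = [r for r in self.rows if r["lost"]]
        gain_only = [r for r in self.rows if r["gained"] and not r["lost"]]
        loss_only = [r for r in self.rows if r["lost"] and not r["gained"]]
        mixed = [r for r in self.rows if r["gained"] and r["lost"]]
        return {
            "n_sites_gained": n_sites_gained,
            "n_sites_lost": n_sites_lost,
            "n_genes_with_gain": len(genes_gain),
            "n_genes_with_loss": len(genes_loss),
            "n_gain_only": len(gain_only),
            "n_loss_only": len(loss_only),
            "n_mixed": len(mixed),
        }

    def gene_row(self, gene: str) -> dict:
        for r in self.rows:
            if r["gene"] == gene:
                return r
        raise KeyError(gene)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": r["gene"],
                    "n_gained": r.get("n_gained", len(r["gained"])),
                    "gained": ";".join(sorted(r["gained"])),
                    "n_lost": r.get("n_lost", len(r["lost"])),
                    "lost": ";".join(sorted(r["lost"])),
                    "status": (
                        "mixed"
                        if r["gained"] and r["lost"]
                        else "gain_only"
                        if r["gained"]
                        else "loss_only"
                        if r["lost"]
                        else "none"
                    ),
                    "annotation": r.get("annotation", ""),
                }
                for r in self.rows
            ]
        )


def aggregate_gainloss(records: list[GainLossRecord]) -> GainLossTable:
    """Group per-variant records by gene (set union), gene id ascending."""
    by_gene: dict[str, dict] = {}
    for rec in records:
        row = by_gene.setdefault(
            rec.gene_id, {"gene": rec.gene_id, "gained": set(), "lost": set(), "annotation": ""}
        )
        row["gained"] |= rec.gained
        row["lost"] |= rec.lost
    return GainLossTable(rows=[by_gene[g] for g in sorted(by_gene)])


def fixture_path() -> Path:
    return Path(str(resources.files("mirsnv.data") / "gainloss_table.tsv"))


def load_gainloss_fixture(path: str | os.PathLike | None = None) -> GainLossTable:
    """Load the packaged per-gene gain/loss reference table.

    Format: TSV with columns gene, relatedness, n_gained, gained, n_lost,
    lost.  miRNA lists are semicolon-separated; "Nil", empty or absent cells
    are empty sets.  n_gained/n_lost transcribe the count printed in each
    cell of the source table (which for one cell exceeds the number of ids
    actually enumerated); totals are computed from these counts.
    """
    path = Path(path) if path is not None else fixture_path()

    def parse_cell(cell: str) -> set[str]:
        cell = cell.strip()
        if not cell or cell.lower() == "nil":
            return set()
        return {m.strip() for m in cell.split(";") if m.strip()}

    expected = ["gene", "relatedness", "n_gained", "gained", "n_lost", "lost"]
    rows: list[dict] = []
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header != expected:
                    raise ValueError(f"unexpected fixture header at line {lineno}: {header}")
                continue
            if len(fields) < 3 or len(fields) > len(expected):
                raise ValueError(f"malformed fixture row at line {lineno}: {line!r}")
            fields += [""] * (len(expected) - len(fields))  # trailing empty cells
            gene, relatedness, n_gained, gained, n_lost, lost = fields
            try:
                n_gained_i, n_lost_i = int(n_gained), int(n_lost)
            except ValueError as exc:
                raise ValueError(f"malformed count at line {lineno}: {line!r}") from exc
            rows.append(
                {
                    "gene": gene,
                    "gained": parse_cell(gained),
                    "lost": parse_cell(lost),
                    "n_gained": n_gained_i,
                    "n_lost": n_lost_i,
                    "annotation": relatedness,
                }
            )
    return GainLossTable(rows=rows)


def write_reports(
    table: GainLossTable,
    out_dir: str | os.PathLike,
    consequences: list[ConsequenceCall] | None = None,
    skips: list[WindowSkip] | None = None,
    deltas: list[StructureDelta] | None = None,
    run_params: dict | None = None,
) -> dict[str, Path]:
    """Emit the consequence-count TSV, per-gene gain/loss TSV, structure TSV,
    JSON summary and an inconsistency log; returns the paths written."""
    from .annotate import tabulate_consequences

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    gl = out_dir / "gainloss_per_gene.tsv"
    table.to_frame().to_csv(gl, sep="\t", index=False)
    paths["gainloss"] = gl

    if consequences is not None:
        cons = out_dir / "consequence_counts.tsv"
        tabulate_consequences(consequences).to_csv(cons, sep="\t", index=False)
        paths["consequences"] = cons

    if skips is not None:
        sk = out_dir / "window_skips.tsv"
        pd.DataFrame(
            [
                {"gene": s.gene_id, "variant": "{}:{}:{}>{}".format(*s.variant_key), "reason": s.reason}
                for s in skips
            ],
            columns=["gene", "variant", "reason"],
        ).to_csv(sk, sep="\t", index=False)
        paths["skips"] = sk

    if deltas is not None:
        st = out_dir / "structure_deltas.tsv"
        pd.DataFrame(
            [
                {
                    "gene": d.gene_id,
                    "variant": "{}:{}:{}>{}".format(*d.variant_key),
                    "ref_energy": d.ref_energy,
                    "alt_energy": d.alt_energy,
                    "delta_energy": d.delta_energy,
                    "bp_distance": d.bp_distance,
                }
                for d in deltas
            ],
            columns=["gene", "variant", "ref_energy", "alt_energy", "delta_energy", "bp_distance"],
        ).to_csv(st, sep="\t", index=False)
        paths["structure"] = st

    mixed = [r["gene"] for r in table.rows if r["gained"] and r["lost"]]
    log = out_dir / "inconsistencies.log"
    with open(log, "w") as fh:
        for gene in mixed:
            fh.write(f"{gene}\tmixed\tboth gains and losses; excluded from gain-only/loss-only lists\n")
    paths["log"] = log

    summary = {
        "totals": table.totals,
        "mixed_genes": mixed,
        "run_params": run_params or {},
    }
    js = out_dir / "summary.json"
    with open(js, "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
    paths["summary"] = js
    return paths
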