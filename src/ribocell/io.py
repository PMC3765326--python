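"""Config files, FASTA export and tabular output."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GenomeDesign, ParameterSet
from .experiments import (
    CaseResult,
    ExperimentConfig,
    InoculationEvent,
    SpreadCriterion,
)
from .rna import RNAMolecule, cleavage_sites

__all__ = [
    "config_to_dict",
    "config_from_dict",
    "save_config",
    "load_config",
    "write_design_fasta",
    "write_cleavage_sites",
    "write_series_tsv",
    "write_snapshot_json",
]


# --------------------------------------------------------------------------
# Config round-trip (flat keys named by the parameter symbols)
# --------------------------------------------------------------------------

def config_to_dict(config: ExperimentConfig) -> dict:
    d = dataclasses.asdict(config.params)
    d.update(
        seed=config.seed,
        steps=config.steps,
        sample_interval=config.sample_interval,
        chromosome_topology=config.chromosome_topology,
        genome_arm=config.genome_arm,
        domain_Rep=config.design.domain_Rep,
        domain_Nsr=config.design.domain_Nsr,
        domain_Npsr=config.design.domain_Npsr,
        domain_Asr=config.design.domain_Asr,
        control_sequence=config.design.control_sequence,
        spread_threshold=config.criterion.threshold,
        spread_window=config.criterion.window,
        schedule=[
            {
                "step": e.step,
                "coord": list(e.coord),
                "kind": e.kind,
                "genome": e.genome,
                "ribozyme_copies": e.ribozyme_copies,
                "chromosome_copies": e.chromosome_copies,
            }
            for e in config.schedule
        ],
    )
    return d


def config_from_dict(d: dict) -> ExperimentConfig:
    d = dict(d)
    param_names = {f.name for f in dataclasses.fields(ParameterSet)}
    params = ParameterSet(**{k: d.pop(k) for k in list(d) if k in param_names})
    design = GenomeDesign(
        domain_Rep=d.pop("domain_Rep", GenomeDesign.domain_Rep),
        domain_Nsr=d.pop("domain_Nsr", GenomeDesign.domain_Nsr),
        domain_Npsr=d.pop("domain_Npsr", GenomeDesign.domain_Npsr),
        domain_Asr=d.pop("domain_Asr", GenomeDesign.domain_Asr),
        control_sequence=d.pop("control_sequence", GenomeDesign.control_sequence),
    )
    schedule = [
        InoculationEvent(
            step=e["step"],
            coord=tuple(e["coord"]),
            kind=e.get("kind", "seeded"),
            genome=e.get("genome", "sense"),
            ribozyme_copies=e.get("ribozyme_copies", 5),
            chromosome_copies=e.get("chromosome_copies", 5),
        )
        for e in d.pop("schedule", [])
    ]
    criterion = SpreadCriterion(
        threshold=d.pop("spread_threshold", 50),
        window=d.pop("spread_window", 0.1),
    )
    return ExperimentConfig(
        params=params,
        design=design,
        seed=d.pop("seed", 1),
        steps=d.pop("steps", 200_000),
        sample_interval=d.pop("sample_interval", 1000),
        chromosome_topology=d.pop("chromosome_topology", "circular"),
        genome_arm=d.pop("genome_arm", "sense"),
        schedule=schedule,
        criterion=criterion,
    )


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def load_config(path: str | Path) -> ExperimentConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


# --------------------------------------------------------------------------
# FASTA / TSV / JSON output
# --------------------------------------------------------------------------

def write_design_fasta(design: GenomeDesign, path: str | Path) -> None:
    """The four domains, both chromosome chains (flagged circular) and the
    control, as a FASTA file."""
    records = [
        SeqRecord(Seq(seq), id=f"domain_{name}",
                  description=f"ribozyme domain {name} topology=linear")
        for name, seq in design.domains.items()
    ]
    records += [
        SeqRecord(Seq(design.sense_sequence), id="chromosome_sense",
                  description="chromosome sense chain topology=circular"),
        SeqRecord(Seq(design.antisense_sequence), id="chromosome_antisense",
                  description="chromosome antisense chain topology=circular"),
        SeqRecord(Seq(design.control_sequence), id="control",
                  description="functionless control topology=circular"),
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def write_cleavage_sites(seq: str, path: str | Path, name: str = "seq") -> None:
    """BED-like 0-based bond intervals of the U|G self-cleavage sites of a
    linear chain."""
    mol = RNAMolecule(seq=seq, circular=False)
    with open(path, "w") as handle:
        handle.write("name\tbond_start\tbond_end\n")
        for bond in cleavage_sites(mol):
            handle.write(f"{name}\t{bond}\t{bond + 1}\n")


def write_series_tsv(result: CaseResult, path: str | Path) -> None:
    result.frame().to_csv(path, sep="\t", index=False)


def write_snapshot_json(result: CaseResult, path: str | Path) -> None:
    """Final-state snapshot: resolved config, final census and histogram."""
    final = result.final
    payload = {
        "config": config_to_dict(result.config),
        "final_step": final.step,
        "census": final.as_row(),
        "length_hist": {str(k): v for k, v in final.length_hist.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2))
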