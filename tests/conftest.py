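"""Shared fixtures: programmatically generated SAM text and a small
simulated dataset reused across test modules."""

from __future__ import annotations

import pytest

from te_spectrum.synthetic_data import SimulationConfig, simulate_all


def sam_text(records: list[dict], chrom_lengths: dict[str, int]) -> str:
    """Build SAM text from record dicts (defaults filled in).

    Keys: qname, flag, chrom, pos (1-based), cigar, tags (list of str).
    """
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom, ln in chrom_lengths.items():
        lines.append(f"@SQ\tSN:{chrom}\tLN:{ln}")
    for r in records:
        seq = r.get("seq", "*")
        tags = r.get("tags", [])
        lines.append(
            "\t".join(
                [
                    r["qname"],
                    str(r.get("flag", 0)),
                    r["chrom"],
                    str(r["pos"]),
                    "255",
                    r["cigar"],
                    "*",
                    "0",
                    "0",
                    seq,
                    "*",
                    *tags,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def write_sam(path, records, chrom_lengths):
    path.write_text(sam_text(records, chrom_lengths))
    return str(path)


MINI_SIM = SimulationConfig(
    seed=7,
    library_size=4000,
    replicates_per_condition=2,
    cpg_coverage_mean=1.0,
    n_te_instances=150,
    n_decoy_junctions=100,
)


@pytest.fixture(scope="session")
def mini_dataset(tmp_path_factory):
    """A small but complete simulated dataset (annotations, truth, files)."""
    outdir = tmp_path_factory.mktemp("mini_sim")
    ann, truth, paths = simulate_all(MINI_SIM, str(outdir))
    return {"config": MINI_SIM, "ann": ann, "truth": truth, "paths": paths}
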