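import numpy as np
import pandas as pd
import pytest

import grsmr


@pytest.fixture(scope="session")
def weights():
    return grsmr.packaged_weights()


@pytest.fixture(scope="session")
def fixture_cohort():
    cohort, _ = grsmr.packaged_fixture()
    return cohort


@pytest.fixture(scope="session")
def big_sim(weights):
    """One 50,000-sample single-stratum null simulation, shared across tests."""
    cfg = grsmr.SimulationConfig(
        strata={"Europe": (25000, 25000)}, causal_log_or=0.0, n_pcs=2, seed=424242)
    return grsmr.simulate_cohort(cfg)


def make_small_cohort(n=40, seed=0, n_pcs=2):
    """Tiny hand-rolled cohort for I/O and plumbing tests."""
    cfg = grsmr.SimulationConfig(
        strata={"Europe": (n // 2, n - n // 2)}, n_pcs=n_pcs, seed=seed)
    return grsmr.simulate_cohort(cfg)


def write_vcf(path, samples, records):
    """Write a minimal VCF with GT calls.

    ``records`` is a list of (chrom, pos, rsid, ref, alt, genotypes) where
    genotypes are per-sample ALT-allele counts (0/1/2 or None=missing).
    """
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for chrom, pos, rsid, ref, alt, gts in records:
        row = [str(chrom), str(pos), rsid, ref, alt, ".", "PASS", ".", "GT"]
        row += [gt_map[g] for g in gts]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")
    return path
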