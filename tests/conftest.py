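import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_genome():
    from aeikit import ReferenceGenome

    return ReferenceGenome({"chr1": "ACGTACGTAC"})


@pytest.fixture
def sam_factory(tmp_path):
    """Write a minimal single-chromosome SAM from (name, pos, cigar, seq[, mapq, qual])."""

    def _write(reads, chrom="chr1", length=200, name="reads.sam"):
        path = tmp_path / name
        lines = ["@HD\tVN:1.6\tSO:coordinate", f"@SQ\tSN:{chrom}\tLN:{length}"]
        for r in reads:
            qname, pos, cigar, seq = r[:4]
            mapq = r[4] if len(r) > 4 else 60
            qual = r[5] if len(r) > 5 else "I" * len(seq)
            lines.append(
                f"{qname}\t0\t{chrom}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t{qual}"
            )
        path.write_text("\n".join(lines) + "\n")
        return str(path)

    return _write
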