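"""Simulation configuration for synthetic splinkerette screens."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


class ConfigError(ValueError):
    """Raised when a SimConfig violates its invariants."""


#: Transposon-derived prefix expected at the start of read 1: the junction
#: fragment of the terminal repeat ending in the duplicated TTAA target site.
TRANSPOSON_PREFIX = "TAGGGTTAA"


@dataclass
class SimConfig:
    """Parameters of a synthetic insertional-mutagenesis screen.

    The defaults describe a desk-scale screen: two sample groups on a small
    genome, sonication fragments of ~250 bp, light PCR duplication, and the
    ~1% of read pairs that do not carry the transposon junction.

    Parameters
    ----------
    seed
        Master seed; every derived random stream is a function of it.
    n_chroms, chrom_length
        Genome shape (chromosomes of equal length, in bp).
    n_genes
        Genes placed on the genome, split evenly across chromosomes.
    fragment_length_mean, fragment_length_sd
        Sonication fragment-length model (truncated normal), bp.
    read_length
        Length of each mate, nt (includes the 9-nt transposon prefix on
        read 1).
    pcr_dup_mean
        Expected extra PCR copies per unique fragment (each fragment is
        emitted ``1 + Poisson(pcr_dup_mean)`` times).
    seq_error_rate
        Per-base substitution probability.
    contaminant_frac
        Fraction of read pairs whose read 1 lacks the transposon prefix.
    barcode_length
        Sample barcode length, nt (emitted in read headers by default).
    noncoding_frac
        Fraction of simulated genes without an annotated CDS.
    groups
        ``[(group_name, n_samples), ...]``.
    n_insertions_per_sample
        Background insertions planted per sample, uniform over TTAA sites.
    diversity_lambda
        λ of the per-site shear-end diversity model ``1 + Poisson(λ)``.
    enriched_genes
        ``[(gene_id, group_name, fold_elevation), ...]``: genes whose
        expected insertion diversity is elevated by ``fold`` in one group.
    inline_barcodes
        Prepend the barcode to read 1 instead of recording it in headers.
    """

    seed: int = 0
    n_chroms: int = 1
    chrom_length: int = 200_000
    n_genes: int = 20
    fragment_length_mean: float = 250.0
    fragment_length_sd: float = 60.0
    read_length: int = 75
    pcr_dup_mean: float = 1.0
    seq_error_rate: float = 0.0005
    contaminant_frac: float = 0.01
    barcode_length: int = 8
    noncoding_frac: float = 0.2
    groups: list[tuple[str, int]] = field(
        default_factory=lambda: [("tumour", 4), ("metastatic", 4)]
    )
    n_insertions_per_sample: int = 100
    diversity_lambda: float = 2.0
    enriched_genes: list[tuple[str, str, float]] = field(default_factory=list)
    inline_barcodes: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("seq_error_rate", "contaminant_frac", "noncoding_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.fragment_length_mean < 20:
            raise ConfigError("fragment_length_mean must be >= 20 bp")
        if self.chrom_length < 10 * self.fragment_length_mean:
            raise ConfigError(
                "chrom_length must be >= 10 x fragment_length_mean "
                f"({self.chrom_length} < {10 * self.fragment_length_mean:.0f})"
            )
        if self.read_length <= len(TRANSPOSON_PREFIX):
            raise ConfigError("read_length must exceed the transposon prefix")
        if self.pcr_dup_mean < 0 or self.diversity_lambda < 0:
            raise ConfigError("rate parameters must be non-negative")
        if not self.groups or any(n < 1 for _, n in self.groups):
            raise ConfigError("each group needs at least one sample")
        names = [g for g, _ in self.groups]
        if len(set(names)) != len(names):
            raise ConfigError("group names must be unique")
        for gene_id, group, fold in self.enriched_genes:
            if group not in names:
                raise ConfigError(f"enriched gene {gene_id}: unknown group {group!r}")
            if fold <= 0:
                raise ConfigError(f"enriched gene {gene_id}: fold must be > 0")

    def sample_ids(self) -> list[str]:
        """Deterministic sample identifiers, e.g. ``tumour_1 .. metastatic_4``."""
        return [f"{g}_{i + 1}" for g, n in self.groups for i in range(n)]

    def sample_groups(self) -> dict[str, str]:
        return {f"{g}_{i + 1}": g for g, n in self.groups for i in range(n)}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = [list(g) for g in self.groups]
        d["enriched_genes"] = [list(e) for e in self.enriched_genes]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "groups" in d:
            d["groups"] = [tuple(g) for g in d["groups"]]
        if "enriched_genes" in d:
            d["enriched_genes"] = [tuple(e) for e in d["enriched_genes"]]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
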