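"""Configuration for the synthetic single-nucleus editing data generator.

The defaults encode the study conditions the generator emulates: a
~1:3 inhibitory:excitatory neuron mix across six cortical regions, sites
predominantly in Alu repeats, a bimodal per-cell edited-allele-frequency
mixture, each site transcribed in ~4.5% of cells, and ~80% of sites
present in a public editing catalog.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ConfigError(ValueError):
    """Raised when a simulation configuration field is invalid."""


@dataclass(frozen=True)
class CellTypeEffect:
    """Per-site log-odds shift of the high-editing mode in one phenotype.

    Applied to ``site_fraction`` of non-SNP sites: cells of ``phenotype``
    have the high-mode weight shifted by ``log_odds`` on the logit scale
    at affected sites.
    """

    phenotype: str = "inhibitory"
    site_fraction: float = 0.2
    log_odds: float = 0.8


def _check_fraction(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name} must be in [0, 1], got {value!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic data generator.

    Parameters
    ----------
    n_cells, n_sites, n_genes
        Problem size.
    phenotype_proportions
        Mapping phenotype -> fraction of cells; must sum to 1.
    region_labels
        Cortical region labels cells are assigned to (uniformly).
    n_subgroups_per_phenotype
        Fine-grained transcriptomic subgroups (e.g. Ex1..Ex8), the unit
        of pseudobulk aggregation together with region.
    alu_fraction, rep_nonalu_fraction
        Fractions of sites placed in Alu and repetitive non-Alu context;
        the remainder is nonrepetitive.
    bimodal_mix
        ``(low_mode_mean, high_mode_mean, high_mode_weight)`` of the
        two-point mixture from which per-cell, per-site editing
        probabilities are drawn.  ``high_mode_weight`` is the *mean*
        across sites; per-site weights are Beta-distributed around it so
        that cross-cell mean edited fractions are positively skewed.
    celltype_effect
        Planted phenotype effect, see :class:`CellTypeEffect`.
    coverage_nb
        ``(mean, shape)`` of the negative-binomial read depth at
        transcribed (site, cell) pairs; variance = mean + mean^2/shape.
    transcription_rate
        Probability that a site is transcribed in a given cell
        (zero-inflation of depth).
    snp_fraction
        Fraction of simulated variant sites that are genomic SNPs of the
        donor (edited fraction ~ dosage/2 in every covered cell).
    antisense_decoy_fraction
        Fraction of sites emitted with the non-cognate variant class
        (e.g. T>C inside a plus-strand gene); these exercise the strand
        filter and are never cataloged.
    overlap_site_fraction
        Fraction of true sites placed inside regions where genes on
        opposite strands overlap; only catalog membership can rescue
        them through the strand filter.
    catalog_fraction
        Fraction of true editing sites present in the main catalog.
    bulk_fraction
        Fraction of true sites present in the secondary "bulk brain"
        catalog used for intersection censuses.
    assoc_genes
        List of ``(gene_index, beta)`` pairs: gene abundance (log10 TPM)
        is generated so that the per-cell global editing index regresses
        on it with slope ~ beta.
    cell_effect_sd
        SD of the per-cell logit-scale editing propensity, the source of
        cell-to-cell editing heterogeneity.
    high_mito_fraction, low_complexity_fraction
        Fractions of cells planted as QC failures (mito fraction > 0.15,
        or detected-gene count below the complexity threshold).
    expr_nb_shape
        Negative-binomial shape of gene expression counts.
    seed
        Master seed; every sub-generator derives its own stream from it.
    """

    n_cells: int = 500
    n_sites: int = 2000
    n_genes: int = 100
    phenotype_proportions: dict = field(
        default_factory=lambda: {"excitatory": 0.75, "inhibitory": 0.25}
    )
    region_labels: tuple = ("BA8", "BA10", "BA17", "BA21", "BA22", "BA41")
    n_subgroups_per_phenotype: int = 8
    alu_fraction: float = 0.70
    rep_nonalu_fraction: float = 0.10
    bimodal_mix: tuple = (0.05, 0.90, 0.40)
    celltype_effect: CellTypeEffect = field(default_factory=CellTypeEffect)
    coverage_nb: tuple = (20.0, 2.0)
    transcription_rate: float = 0.045
    snp_fraction: float = 0.05
    antisense_decoy_fraction: float = 0.05
    overlap_site_fraction: float = 0.03
    catalog_fraction: float = 0.80
    bulk_fraction: float = 0.69
    assoc_genes: tuple = ()
    cell_effect_sd: float = 0.30
    high_mito_fraction: float = 0.01
    low_complexity_fraction: float = 0.01
    expr_nb_shape: float = 3.0
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_cells < 1:
            raise ConfigError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.n_sites < 1:
            raise ConfigError(f"n_sites must be >= 1, got {self.n_sites}")
        if self.n_genes < 1:
            raise ConfigError(f"n_genes must be >= 1, got {self.n_genes}")
        if not self.phenotype_proportions:
            raise ConfigError("phenotype_proportions must be non-empty")
        total = sum(self.phenotype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"phenotype_proportions must sum to 1 (got {total!r})"
            )
        for name in (
            "alu_fraction",
            "rep_nonalu_fraction",
            "transcription_rate",
            "snp_fraction",
            "antisense_decoy_fraction",
            "overlap_site_fraction",
            "catalog_fraction",
            "bulk_fraction",
            "high_mito_fraction",
            "low_complexity_fraction",
        ):
            _check_fraction(name, getattr(self, name))
        for ph, p in self.phenotype_proportions.items():
            _check_fraction(f"phenotype_proportions[{ph!r}]", p)
        if self.alu_fraction + self.rep_nonalu_fraction > 1.0 + 1e-12:
            raise ConfigError(
                "alu_fraction + rep_nonalu_fraction must not exceed 1"
            )
        low, high, weight = self.bimodal_mix
        _check_fraction("bimodal_mix.low_mode_mean", low)
        _check_fraction("bimodal_mix.high_mode_mean", high)
        _check_fraction("bimodal_mix.high_mode_weight", weight)
        mean, shape = self.coverage_nb
        if mean <= 0:
            raise ConfigError(f"coverage_nb mean must be > 0, got {mean!r}")
        if shape <= 0:
            raise ConfigError(f"coverage_nb shape must be > 0, got {shape!r}")
        _check_fraction(
            "celltype_effect.site_fraction", self.celltype_effect.site_fraction
        )
        if self.celltype_effect.phenotype not in self.phenotype_proportions:
            raise ConfigError(
                "celltype_effect.phenotype "
                f"{self.celltype_effect.phenotype!r} is not a phenotype"
            )
        for g, _beta in self.assoc_genes:
            if not (0 <= int(g) < self.n_genes):
                raise ConfigError(f"assoc_genes index {g} out of range")
        if self.n_subgroups_per_phenotype < 1:
            raise ConfigError("n_subgroups_per_phenotype must be >= 1")
        return self

    def rng(self, stream: str):
        """Deterministic per-component RNG derived from the master seed."""
        import numpy as np

        # stable string -> integer stream key, independent of PYTHONHASHSEED
        key = sum(ord(c) * 31**i for i, c in enumerate(stream)) % (2**31)
        return np.random.default_rng([self.seed % (2**31), key])
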