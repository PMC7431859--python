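"""Patient-specific MHC presentation scoring and immune-selection biostatistics.

The package scores how well a cancer patient's inherited MHC class I and
class II molecules can present recurrent driver mutations (the PHBR score:
per patient per mutation, the harmonic mean across the patient's scoring
molecules of each molecule's best percentile-rank over all mutant peptide
windows), and provides the statistical machinery to ask whether presentation
interacts with sex and age to shape which mutations are observed in tumors:
group comparisons with permutation controls, and mixed-effects logistic
selection models with PHBR-by-covariate interactions.

Synthetic cohort generation with known ground truth makes every stage
testable end to end.
"""

from importlib.metadata import PackageNotFoundError, version

try:
    __version__ = version("immunoselect")
except PackageNotFoundError:  # pragma: no cover - source tree use
    __version__ = "0+unknown"

from . import hla, peptides, phbr, stats, glmm, simulate, signatures, expression, pipeline  # noqa: F401,E402
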