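"""Test helpers: thin aliases over the package's validation fixtures."""

from cladelink.reference import random_validation_pedigree as random_small_pedigree  # noqa: F401
from cladelink.reference import phase_known_family  # noqa: F401
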