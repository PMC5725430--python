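"""swdeeg: swarm decomposition + spatial clustering + CNN for HD-EEG.

A pipeline for classifying visual-stimulus categories from high-density
EEG: trials are decomposed into oscillatory modes by swarm decomposition
(SWD), electrodes are clustered into the 19 10-20 regions to form
image-like tensors, and a small convolutional network performs 2- or
4-class classification.  A synthetic HD-EEG generator with controllable
class effects makes every stage testable end to end.
"""

__version__ = "0.1.0"

from . import (clustering, cnn, evaluation, montage, pipeline, preprocess,
               simulate, swd)

__all__ = [
    "__version__",
    "clustering",
    "cnn",
    "evaluation",
    "montage",
    "pipeline",
    "preprocess",
    "simulate",
    "swd",
]
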