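"""Sequential network container with access to intermediate activations.

Beyond plain forward/backward, the container supports the operations the
interpretability stage needs:

* ``forward`` with ``record=True`` keeps every layer's output, so internal
  activations can be read off by layer name;
* ``gradient_at`` returns the gradient of a scalar readout of the output with
  respect to a named layer's activation (backpropagation stopped part-way);
* ``forward_from`` re-runs only the layers above a named layer, starting from
  a supplied activation — used by finite-difference checks of those gradients.
"""

from __future__ import annotations

import numpy as np

from .layers import Layer

__all__ = ["Sequential"]


class Sequential:
    def __init__(self, layers: list[Layer], name: str = "net"):
        self.layers = list(layers)
        self.name = name
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate layer names in {name}: {names}")

    # -- introspection ------------------------------------------------
    def layer_names(self) -> list[str]:
        return [l.name for l in self.layers]

    def _index(self, layer_name: str) -> int:
        for i, l in enumerate(self.layers):
            if l.name == layer_name:
                return i
        raise KeyError(f"no layer named {layer_name!r} in {self.name}; have {self.layer_names()}")

    # -- forward / backward -------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False, record: bool = False) -> np.ndarray:
        self._recorded: dict[str, np.ndarray] | None = {} if record else None
        for layer in self.layers:
            x = layer.forward(x, training=training)
            if record:
                self._recorded[layer.name] = x
        return x

    def activation(self, layer_name: str) -> np.ndarray:
        if self._recorded is None:
            raise RuntimeError("call forward(..., record=True) first")
        return self._recorded[layer_name]

    def backward(self, dy: np.ndarray, stop_after: str | None = None) -> np.ndarray:
        """Backpropagate ``dy`` through the network (most recent forward).

        With ``stop_after`` set, stops once the gradient with respect to that
        layer's *output* is available and returns it.
        """
        stop = self._index(stop_after) if stop_after is not None else -1
        for i in range(len(self.layers) - 1, stop, -1):
            dy = self.layers[i].backward(dy)
        return dy

    def gradient_at(self, x: np.ndarray, layer_name: str, output_grad: np.ndarray) -> np.ndarray:
        """d(output_grad . output) / d(activation after ``layer_name``)."""
        self.forward(x, training=False)
        return self.backward(output_grad, stop_after=layer_name)

    def forward_from(self, layer_name: str, activation: np.ndarray) -> np.ndarray:
        """Run the layers strictly above ``layer_name`` on a given activation."""
        start = self._index(layer_name) + 1
        x = activation
        for layer in self.layers[start:]:
            x = layer.forward(x, training=False)
        return x

    # -- parameters ----------------------------------------------------
    def parameters(self):
        """Yield (layer, key, array) triples for every trainable parameter."""
        for layer in self.layers:
            for key in layer.params:
                yield layer, key, layer.params[key]

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for layer in self.layers:
            for key, val in layer.params.items():
                state[f"{layer.name}.{key}"] = val.copy()
            for extra in ("running_mean", "running_var"):
                if hasattr(layer, extra):
                    state[f"{layer.name}.{extra}"] = getattr(layer, extra).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for layer in self.layers:
            for key in layer.params:
                layer.params[key] = state[f"{layer.name}.{key}"].copy()
            for extra in ("running_mean", "running_var"):
                if hasattr(layer, extra):
                    setattr(layer, extra, state[f"{layer.name}.{extra}"].copy())

    def n_parameters(self) -> int:
        return sum(p.size for _, _, p in self.parameters())
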