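# Berrera et al. empirical 20x20 residue contact-potential matrix
# (lower triangle; row/column order as published).  Units: statistical
# contact-energy units.  Lines drawn in the published table group the
# first ten rows; boldfaced (hydrophobic) names there are Met Phe Ile
# Leu Val Trp Tyr Ala Gly Pro.
Cys -3.477
Met -2.24 -1.901
Phe -2.424 -2.304 -2.467
Ile -2.41 -2.286 -2.53 -2.691
Leu -2.343 -2.208 -2.491 -2.647 -2.501
Val -2.258 -2.079 -2.391 -2.568 -2.447 -2.385
Trp -2.08 -2.09 -2.286 -2.303 -2.222 -2.097 -1.867
Tyr -1.892 -1.834 -1.963 -1.998 -1.919 -1.79 -1.834 -1.335
Ala -1.7 -1.517 -1.75 -1.872 -1.728 -1.731 -1.565 -1.318 -1.119
Gly -1.101 -0.897 -1.034 -0.885 -0.767 -0.756 -1.142 -0.818 -0.29 0.219
Thr -1.243 -0.999 -1.237 -1.36 -1.202 -1.24 -1.077 -0.892 -0.717 -0.311 -0.617
Ser -1.306 -0.893 -1.178 -1.037 -0.959 -0.933 -1.145 -0.859 -0.607 -0.261 -0.548 -0.519
Gln -0.835 -0.72 -0.807 -0.778 -0.729 -0.642 -0.997 -0.687 -0.323 0.033 -0.342 -0.26 0.054
Asn -0.788 -0.658 -0.79 -0.669 -0.524 -0.673 -0.884 -0.67 -0.371 -0.23 -0.463 -0.423 -0.253 -0.367
Glu -0.179 -0.209 -0.419 -0.439 -0.366 -0.335 -0.624 -0.453 -0.039 0.443 -0.192 -0.161 0.179 0.16 0.933
Asp -0.616 -0.409 -0.482 -0.402 -0.291 -0.298 -0.613 -0.631 -0.235 -0.097 -0.382 -0.521 0.022 -0.344 0.634 0.179
His -1.499 -1.252 -1.33 -1.234 -1.176 -1.118 -1.383 -1.222 -0.646 -0.325 -0.72 -0.639 -0.29 -0.455 -0.324 -0.664 -1.078
Arg -0.771 -0.611 -0.805 -0.854 -0.758 -0.664 -0.912 -0.745 -0.327 -0.05 -0.247 -0.264 -0.042 -0.114 -0.374 -0.584 -0.307 0.2
Lys -0.112 -0.146 -0.27 -0.253 -0.222 -0.2 -0.391 -0.349 0.196 0.589 0.155 0.223 0.334 0.271 -0.057 -0.176 0.388 0.815 1.339
Pro -1.196 -0.788 -1.076 -0.991 -0.771 -0.886 -1.278 -1.067 -0.374 -0.042 -0.222 -0.199 -0.035 -0.018 0.257 0.189 -0.346 -0.023 0.661 0.129
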