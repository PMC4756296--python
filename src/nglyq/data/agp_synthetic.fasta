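>AGP1_SYNTH synthetic stand-in modeled on human alpha-1-acid glycoprotein (tryptic context for ENGTISR and CANLVPVPITNATLDQITGK; not the UniProt sequence)
MLAFKCANLVPVPITNATLDQITGKWFYIASAFRNEEYNKSVQEIQATFFYFTPNKTEDT
IFLRQDQCIYNTTYLNVQRENGTISRYVGGQEHFAHLLILREQLGEFYEALDCLRSDVVY
TDWKDTK
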