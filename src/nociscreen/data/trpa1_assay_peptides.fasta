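>TRPA1_pep1 decapeptide substrate, acceptor T at window position 4
YGNTPLHCAA
>TRPA1_pep2 decapeptide substrate, acceptor S at window position 4
NMMSPLHIAV
>TRPA1_pep3 decapeptide substrate, acceptor S at window position 4
KKASPLHLAV
>TRPA1_pep4 decapeptide substrate, acceptor T at window position 4
DGCTPLHYAC
>TRPA1_pep5 decapeptide substrate, acceptor S at window position 4
DKKSPLHFAA
>TRPA1_pep6 decapeptide substrate, acceptor T at window position 4
HGMTPLHLAA
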