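>ectC_ref1 ectC designated reference (synthetic stand-in)
DSIIPLSEARDTYDVVKHNNDDVEPDKITQIISEMAARPFDSNLANVTTRRVADIQEIKLLGAMVFAQSS
TPLKTAGSGSQIREYNATIQTLKASPDRKTDEIQVNADVVGLLHPKYDHLRGFTRHEALL
>ectC_ref2 ectC homolog (synthetic stand-in)
EKPKPLSEAMDTYDVVKNNQDDVEPDKWTQIISEMAARPFDSNHANVTNRRVIDIQLIKLLGAMDFAQSS
HNLKTKGEGSQIREYNATIPTRRASPDRKTDEVQVNAEVVGLLHHKYHHVRGFTYHQAML
>ectC_ref3 ectC homolog (synthetic stand-in)
VSIIPLSEGRDMYDLVKHNNNDVDPDKITQIISEMFVRPFNSNLRNITTRSVADIQEIQILGAIVYRRSS
YPLKQVGSGSQIPEYNATIHTMKMGAINMQPRIQHNADVVGLLHPFIAHLKGKTRHMAVL
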