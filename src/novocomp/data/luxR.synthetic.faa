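>luxR_ref1 luxR designated reference (synthetic stand-in)
RSKTWALGEYLARERAKFDGHFLLSIRGTQFMQERGGTKLAVKAQCTEGLAGQTTSLRGPEMTTGGRDKL
IKSVGMFEPRSHKTLGPRKKSPGDAVGGKTLKDEFECTAGILPFKKLDLHLMGTFDAYPYRIKYESRRIW
LDVTVAQLHSFELYMTSVSMPRNLKLLNLVKLLVSFHQNAAAAPSDTGVCWFELQRLVQLQNVFLVTALR
LYVQLLTAAPTTGPVFFIPAPSLPVTNTER
>luxR_ref2 luxR homolog (synthetic stand-in)
RMITWALGEWLANEQAVFDGSFLLSYRGDKQMQPRGGAKLIVTAQIQEALTWHTTSLRGFEMGVGGRDVL
RKSEGMWRPVSHKTLGPKERNPGDAVGAKTLEDSWECTAVKLHFHHLDFHLMGTFDAEPYRIKYESARIW
MDVAVAQLHCFELYMISVSMPRNIKLYQMNKLLVSFHQNAAAVPIDTGPCTFEMFRTVQLQNVFLVTTLK
TYVQLIIAAPTSGTVYGIPAPSLDVQNCQT
>luxR_ref3 luxR homolog (synthetic stand-in)
RSKAWALGEYLAMERAKFDGHILLVIYFTQFQQERGGTKLLVKAQMTEGLAGNTTSLKGPLITTGGRKML
IKDVSLIEPRSHRTLGPRKRSPGDIVGGSTLKDENHCTAGILPFWKLPLHLMGPFDAYRYRIKYESFRDW
DWVTIAQLHGFEHRMTNVSRPRNLKKMNSVKILVPFVLNAAEPPSDTGVCWFEVQRLVQLQNVHVITALR
LYVQCLTAAPTTGSILQIPAPSLDVTDEER
>luxR_ref4 luxR homolog (synthetic stand-in)
RSRSWALNEYIARQRAKFDYHFLLHIRGTAGMQNRGGTKLAIKAQCIEGLAGITTSLRNPEMTTVGREKL
IKSVAQFETRSRNTLGPDEKSGGECVGGKRLKDMFETTAGFLPFQKLDLHLEGTFDAYAYRIKQASKRLW
LDMHAANLHSVELVMSSRSMPMALKMIETVKLLVEFHQNAQGAPSGMKVCWFELQKLVQLQNVDLVTALR
LSVQYITAEPTTGMVFFIPARKLPVRNTKR
>luxR_ref5 luxR homolog (synthetic stand-in)
RNKTWALAEYLTRERAKEHCHFMLSIRGTSFMQEETGHKLAVKAQCTEPLAGQKVSMVGNELTTSGRDKL
IRSVGRFRPRSHKTLGPRKKSFTDAVGGKTVMDEYKCTAQLMPFKHLTLHFDFQRDAYPYRILFEQRRVW
TDVQVAVLYLYELYMTSLSMQRNLKTWNMVKLLPSFYQNTAAAPSDTGFAWFELQRLFQRQNVFLSTALR
LYVQMLEDAPTTGPVFFYNAPSWPVANDER
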