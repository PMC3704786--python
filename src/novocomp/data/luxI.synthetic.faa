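>luxI_ref1 luxI designated reference (synthetic stand-in)
AEGNSYLEVIAEGQLVDIHFQPVRVALFIPHELWDLIYQKCQSPNGRNAAACSVNLGTKMEKEVSPAAEY
ANMTSPILGVVAKGGVPSDGGVILQEQGFMLSKIVAGWWAKPDSERGTERDIVFHAELTPSKGCVYLHIE
KFFAKFGAHINRRFFAVISPGAMLGVSFLQVVLPGSGTVAKTKNTYQRGHAAREDKVERY
>luxI_ref2 luxI homolog (synthetic stand-in)
AEGTSYQGVIAEGDDIDEHFQPVRVALFLKHELWKLIYLKCQSHNGRPRYACSVNLGQKMEKRVSPAARY
ANMTAPILVVVAFWGVVWDGSVMMEEQGFMNSKIVAERWAVQLSKMGTERQIVFEAELTPSKWCVYIAIK
LIFAKFGAHLWRRPFAVISPGAMYGASFLQTVLVDSGTVQNTKNTYDRGHAAREDKIERY
>luxI_ref3 luxI homolog (synthetic stand-in)
AEGVSFCEVIIEGQLMDMHFYPCRVAMFIDSELWDLAYDQCQSNNGKNAAAMSVNMGTKASKQMSPGAEH
APQTSPILGPVARFGVVQDGGRILGEQGFMLAKIVRGWWGMPESEKGFERDIVFHAELTPSKKCIYMWIE
KEFGAEGAYIEHRFYAVISPGAMLGVSFVQVFAPGSGTVMKAKHIAQRDHAARADKMERY
>luxI_ref4 luxI homolog (synthetic stand-in)
AEGVSYTYVAAYKQLVDIECQMFRVCLFIPHMLWDLIYQKSQDPFSRNAAMQSINLGTFIEKENSPAAEY
NNMTNSFLVVVAKGSVPSQQGSILQEQGFVAAKIVAGWWCKCDAERGTERDIVFHAHYTTSKGIKLTHIE
KVWAHCGSHINRNFMAVISPGAMIWMSFLQVVLPGSWTVADQENAYDRGLAASEGEEEQW
>luxI_ref5 luxI homolog (synthetic stand-in)
AEGRSYLQIMAEGMLCDFHFCPIRIAKFIPHEMWELIYEKCQSEHGEEIAYCDAPLPTFMENSVSPAAEY
ACYTSPILGVVAKGNVPSDEGVIMQEQGYMLSEIVDGWWNIPDSSRGTERSIPFHHKLTPSKGCVFLHIE
KFFFLKGAHVNRRYGAVISPGEMLGVSFEQLVPPNSGTRAKTKNYYERGHNARDDKVDRK
>luxI_ref6 luxI homolog (synthetic stand-in)
EEGNSYLDTMTEGQLVDIHFQHVRFAVFIDHELWDVIYQKCQISNGKQSAKCSVNVATKMEKPVIPAAEY
AHMTSPIMRVVIVGGVDEDGGVIFQEQGFMMMISVGAFWQKPDCERATEMDIEFLADMTASKGCVGLNMF
KFMMMFGAHINRRFFALDSPGAMLGVSFFQVVQPSSGYVAKTKNTYQRGHAAREDKVERF
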