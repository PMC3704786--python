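>ectA_ref1 ectA designated reference (synthetic stand-in)
RDCQDAALHMALGNEDDSDLLARTEKRGWQGYALTNGFVHSGKVIPYVDKDQLVKKGPIVFVTDTGVTAR
FEEIADPAKARAYLHPEYRYVANPTVFIDYPCHFVMQKVSFLGVEIADLQMPPPAYFNDVEKYNLKQAAA
ERAYWFVCEHFDGIMENTMRLI
>ectA_ref2 ectA homolog (synthetic stand-in)
IDCQDMAFNMAMGNEDDSDLLAQCEKKGWQNYGLTNGFVHSGKGMQYVAKDQQYKSGPIVYVTDTGPTTR
APEITDGAKARAYLHPSYRYVANPTCYIEYDLHFLMQKASFLGVEIADVQKPPPNYFDDVKKYNLKQAAA
ERAYWCVWEHFDKICENTMRLI
>ectA_ref3 ectA homolog (synthetic stand-in)
LDIQDAKLMIALGNEDPSSLLRRTEKRGWQGYAVTNGFIHSRPVIPYVDKDMLVKKGPIVFVTDRGVTRR
FEEIAPPRKARAYHVHEYRWHINPTVMIDYPFYFVMQKVSFLSVEFADLQVEPPAYYHSVEKYNLKQIAA
VEALWFVCQAYDGQMEQDSRWI
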